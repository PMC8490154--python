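"""Change-point detection in mass traces and plateau kinetics.

Mass change points are found with the Kalafut-Visscher algorithm:
greedy insertion of the change point that most decreases the Schwarz
(Bayesian) information criterion of a piecewise-constant Gaussian model
with pooled variance, iterated until no insertion decreases it.  Because
the raw algorithm is sensitive to series length and to points near the
series boundaries, traces are concatenated, cut into subsets of equal
length l, and the cut positions are shifted circularly through all l
offsets; a change point is accepted where the fraction of iterations
reporting it (within +/- 1 frame) reaches f.  Trajectory joints are hard
boundaries and are never reported as steps.

Plateaus between accepted steps are classified by the sign of the
following mass change (attachment / detachment); the final plateau of an
uncensored trajectory is the particle's membrane release.  Average dwell
times are computed from the dwell histogram as

    t_bar = sum(N_i t_i) / sum(N_i) - t_mode

with dwell times below 5 frames excluded and the standard error from
10,000 bootstrap resamples of the plateau list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "kv_changepoints",
    "consensus_steps",
    "Plateau",
    "Step",
    "PlateauSet",
    "classify_plateaus",
    "mean_dwell_time",
    "oligomer_dwell_split",
]

DEFAULT_SUBSET_LENGTH = 1000
DEFAULT_CONSENSUS_FRACTION = 0.25
DEFAULT_MIN_DWELL_FRAMES = 5
DEFAULT_N_BOOT = 10000
DEFAULT_MASS_WINDOWS = {"dimer": (66.0, 17.0), "tetramer": (132.0, 17.0)}


def _segment_sse(css, cs, i, j):
    """Sum of squared residuals about the mean of series[i:j]."""
    n = j - i
    return (css[j] - css[i]) - (cs[j] - cs[i]) ** 2 / n


def _best_split(css, cs, i, j):
    """Best internal split of segment [i, j): (gain, index) or (0, -1)."""
    if j - i < 2:
        return 0.0, -1
    ks = np.arange(i + 1, j)
    nl = ks - i
    nr = j - ks
    left = (css[ks] - css[i]) - (cs[ks] - cs[i]) ** 2 / nl
    right = (css[j] - css[ks]) - (cs[j] - cs[ks]) ** 2 / nr
    total = _segment_sse(css, cs, i, j)
    gains = total - (left + right)
    k = int(np.argmax(gains))
    return float(gains[k]), int(ks[k])


def kv_changepoints(series: Sequence[float]) -> list[int]:
    """Kalafut-Visscher change points of a 1-D series.

    Returns sorted indices c such that series[c] starts a new constant
    segment.  With k change points the piecewise-constant Gaussian model
    has 2k + 2 free parameters (k segment-boundary locations, k + 1
    means, one pooled variance), giving
    BIC = (2k + 2) ln N + N ln(SSE / N); an insertion is accepted only
    while it strictly decreases the BIC.  Deterministic: the largest
    SSE-reduction wins, ties by lowest index.
    """
    y = np.asarray(series, dtype=float)
    n = y.size
    if n < 2:
        return []
    cs = np.concatenate([[0.0], np.cumsum(y)])
    css = np.concatenate([[0.0], np.cumsum(y**2)])

    sse = _segment_sse(css, cs, 0, n)
    bounds = [0, n]
    best = {(0, n): _best_split(css, cs, 0, n)}
    log_n = np.log(n)
    while True:
        gain_best, seg_best = 0.0, None
        for a, b in zip(bounds[:-1], bounds[1:]):
            g, k = best[(a, b)]
            if k >= 0 and g > gain_best:
                gain_best, seg_best = g, (a, b, k)
        if seg_best is None:
            break
        a, b, k = seg_best
        new_sse = sse - gain_best
        # BIC change for one extra change point
        if new_sse <= 0:
            delta = -np.inf if gain_best > 0 else np.inf
        else:
            delta = 2.0 * log_n + n * np.log(new_sse / sse)
        if delta >= 0:
            break
        sse = new_sse
        bounds.insert(bounds.index(b), k)
        del best[(a, b)]
        best[(a, k)] = _best_split(css, cs, a, k)
        best[(k, b)] = _best_split(css, cs, k, b)

    # Refinement: greedy insertion cannot revise earlier choices, so
    # (a) re-localise each change point to the optimal split between its
    # neighbours and (b) drop any change point whose removal decreases
    # the BIC.  Both moves are deterministic and strictly decrease the
    # criterion, so the loop terminates.
    for _ in range(50):
        changed = False
        for idx in range(1, len(bounds) - 1):
            a, b = bounds[idx - 1], bounds[idx + 1]
            _, k = _best_split(css, cs, a, b)
            if k >= 0 and k != bounds[idx]:
                new = (_segment_sse(css, cs, a, k) + _segment_sse(css, cs, k, b))
                old = (_segment_sse(css, cs, a, bounds[idx])
                       + _segment_sse(css, cs, bounds[idx], b))
                if new < old:
                    sse += new - old
                    bounds[idx] = k
                    changed = True
        for idx in range(len(bounds) - 2, 0, -1):
            a, b = bounds[idx - 1], bounds[idx + 1]
            merged = _segment_sse(css, cs, a, b)
            split = (_segment_sse(css, cs, a, bounds[idx])
                     + _segment_sse(css, cs, bounds[idx], b))
            sse_without = sse + merged - split
            if sse_without <= 0 or sse <= 0:
                continue
            delta = -2.0 * log_n + n * np.log(sse_without / sse)
            if delta < 0:
                sse = sse_without
                del bounds[idx]
                changed = True
        if not changed:
            break
    return bounds[1:-1]


def _collapse_counts(counts: np.ndarray, n_iter: int, fraction: float,
                     forbidden: set[int]) -> dict[int, float]:
    """Accept positions whose +/-1-frame neighbourhood reaches the fraction."""
    L = counts.size
    window = counts.copy().astype(float)
    window[1:] += counts[:-1]
    window[:-1] += counts[1:]
    frac = window / n_iter
    order = np.lexsort((np.arange(L), -window))
    accepted: dict[int, float] = {}
    for pos in order:
        if counts[pos] == 0 or frac[pos] < fraction:
            continue
        if pos in forbidden:
            continue
        if any(abs(pos - a) <= 1 for a in accepted):
            continue
        accepted[int(pos)] = float(frac[pos])
    return accepted


def consensus_steps(
    traces: Sequence[np.ndarray],
    subset_length: int = DEFAULT_SUBSET_LENGTH,
    fraction: float = DEFAULT_CONSENSUS_FRACTION,
) -> list[list[tuple[int, float]]]:
    """Consensus Kalafut-Visscher steps over concatenated traces.

    The traces (kept in the given order) are concatenated; for each of
    the ``subset_length`` circular shifts the concatenated series is cut
    into subsets of that length and change points are detected per
    contiguous piece (subset cuts and trajectory joints both bound the
    pieces).  A change point is accepted where the fraction of iterations
    reporting it within +/- 1 frame is at least ``fraction``.

    Returns, per trace, a list of ``(local_index, consensus_fraction)``
    with local_index the first frame of the new plateau.
    """
    traces = [np.asarray(t, dtype=float) for t in traces]
    if not traces:
        return []
    lengths = [t.size for t in traces]
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    series = np.concatenate(traces)
    L = series.size
    l_eff = subset_length
    if subset_length > L:
        import warnings

        warnings.warn(
            f"subset length {subset_length} exceeds concatenated length {L}; "
            "falling back to a single subset", stacklevel=2)
        l_eff = L

    # trajectory joints: forbidden as reported steps (incl. the circular
    # wrap-around junction); KV re-discovers them inside the subsets as
    # mass jumps between unrelated traces, which is intended
    joints = set(int(o) % L for o in offsets)
    forbidden = set()
    for j in joints:
        forbidden.update(((j - 1) % L, j, (j + 1) % L))
    counts = np.zeros(L, dtype=np.int32)

    for shift in range(l_eff):
        rolled = np.roll(series, -shift)
        for m in range(0, L, l_eff):
            seg = rolled[m:m + l_eff]
            if seg.size < 2:
                continue
            for c in kv_changepoints(seg):
                counts[(shift + m + c) % L] += 1

    accepted = _collapse_counts(counts, l_eff, fraction, forbidden)

    per_trace: list[list[tuple[int, float]]] = [[] for _ in traces]
    for pos, frac in sorted(accepted.items()):
        ti = int(np.searchsorted(offsets, pos, side="right") - 1)
        local = pos - int(offsets[ti])
        if 0 < local < lengths[ti]:
            per_trace[ti].append((local, frac))
    return per_trace


@dataclass
class Plateau:
    start: int
    end: int  # exclusive
    mean_mass_kda: float
    dwell_frames: int
    label: str  # attachment | detachment | release | censored


@dataclass
class Step:
    frame: int
    dmass_kda: float
    consensus_fraction: float


@dataclass
class PlateauSet:
    plateaus: list
    steps: list
    censored: bool = False


def classify_plateaus(
    trace: np.ndarray,
    steps: Sequence[tuple[int, float]],
    censored: bool = False,
) -> PlateauSet:
    """Label the constant-mass plateaus of one trace.

    A plateau followed by a mass increase is an attachment plateau, one
    followed by a decrease a detachment plateau; the final plateau is the
    membrane release unless the trajectory is censored (particle touched
    the video boundary in time), in which case it carries no release
    label.  The initial membrane-binding mass is not itself a step.
    """
    trace = np.asarray(trace, dtype=float)
    cps = sorted(int(i) for i, _ in steps)
    fracs = {int(i): float(f) for i, f in steps}
    bounds = [0] + cps + [trace.size]
    means = [float(np.mean(trace[a:b])) for a, b in zip(bounds[:-1], bounds[1:])]

    step_objs = [
        Step(frame=c, dmass_kda=means[k + 1] - means[k],
             consensus_fraction=fracs[c])
        for k, c in enumerate(cps)
    ]
    plateaus = []
    for k, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        if k < len(step_objs):
            label = "attachment" if step_objs[k].dmass_kda > 0 else "detachment"
        else:
            label = "censored" if censored else "release"
        plateaus.append(Plateau(start=a, end=b, mean_mass_kda=means[k],
                                dwell_frames=b - a, label=label))
    return PlateauSet(plateaus=plateaus, steps=step_objs, censored=censored)


def mean_dwell_time(
    dwell_frames: Sequence[int],
    frame_time_s: float,
    min_dwell_frames: int = DEFAULT_MIN_DWELL_FRAMES,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
) -> tuple[float, float]:
    """Average dwell time (s) above the most frequent dwell, with bootstrap SE.

    Dwells shorter than ``min_dwell_frames`` are excluded (short plateaus
    are unresolvable at the single-frame mass noise level).  The mean is
    the count-weighted mean dwell minus the most frequent dwell time; the
    SE resamples the plateau list (not histogram bins) ``n_boot`` times.
    """
    d = np.asarray(dwell_frames, dtype=int)
    d = d[d >= min_dwell_frames]
    if d.size == 0:
        raise ValueError("no dwell times remain after the minimum-dwell exclusion")

    def _tbar(dd: np.ndarray) -> float:
        vals, cnts = np.unique(dd, return_counts=True)
        t = vals * frame_time_s
        t_mode = t[np.argmax(cnts)]  # ties: smallest dwell (np.argmax is first)
        return float(np.sum(cnts * t) / np.sum(cnts) - t_mode)

    tbar = _tbar(d)
    if n_boot <= 0:
        return tbar, float("nan")
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        boot[b] = _tbar(rng.choice(d, size=d.size, replace=True))
    return tbar, float(np.std(boot))


def oligomer_dwell_split(
    plateaus: Sequence[Plateau],
    windows: dict[str, tuple[float, float]] | None = None,
) -> dict[str, dict[str, list[int]]]:
    """Bin plateau dwell times by species mass window and plateau label.

    ``windows`` maps species name to (centre, half-width) in kDa; the
    defaults are the dimer (66 +/- 17 kDa) and tetramer (132 +/- 17 kDa)
    windows.  Edges are inclusive; overlapping windows are rejected.
    """
    if windows is None:
        windows = DEFAULT_MASS_WINDOWS
    items = sorted(windows.items(), key=lambda kv: kv[1][0])
    for (_, (c1, h1)), (_, (c2, h2)) in zip(items[:-1], items[1:]):
        if c1 + h1 > c2 - h2:
            raise ValueError("mass windows overlap")
    out: dict[str, dict[str, list[int]]] = {
        name: {"attachment": [], "detachment": [], "release": []}
        for name in windows
    }
    for p in plateaus:
        if p.label not in ("attachment", "detachment", "release"):
            continue
        for name, (center, half) in windows.items():
            if center - half <= p.mean_mass_kda <= center + half:
                out[name][p.label].append(p.dwell_frames)
                break
    return out
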