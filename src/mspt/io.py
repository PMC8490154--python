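"""Video and table I/O plus acquisition-style preprocessing.

Videos travel as multi-page TIFF (interchange) or HDF5 (canonical
container: dataset ``frames`` with attributes ``pixel_size_nm`` and
``frame_time_s``).  Trajectory and summary tables are plain CSV.  Frame
averaging and pixel binning reproduce the acquisition-side reduction
(e.g. fivefold frame averaging of a 1 kHz stream -> 200 Hz, fourfold
binning of 21.1 nm native pixels -> 84.4 nm) and scale the metadata
accordingly.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .video import CameraVideo

__all__ = [
    "read_video",
    "write_video",
    "frame_average",
    "pixel_bin",
    "write_manifest",
    "read_manifest",
]

_REQUIRED_ATTRS = ("pixel_size_nm", "frame_time_s")


def write_video(video: CameraVideo, path) -> None:
    """Write a video with its metadata; format chosen by file suffix."""
    path = Path(path)
    meta = {"pixel_size_nm": float(video.pixel_size_nm),
            "frame_time_s": float(video.frame_time_s)}
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, video.frames, metadata=meta)
    elif path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("frames", data=video.frames)
            for k, v in meta.items():
                ds.attrs[k] = v
    else:
        raise ValueError(f"unsupported video format: {path.suffix}")


def read_video(path) -> CameraVideo:
    """Read a TIFF or HDF5 video; metadata attributes are mandatory."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tif:
            frames = tif.asarray()
            meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
        missing = [a for a in _REQUIRED_ATTRS if a not in meta]
        if missing:
            raise ValueError(
                f"{path} lacks required metadata attributes: {missing}")
        return CameraVideo(frames, float(meta["pixel_size_nm"]),
                           float(meta["frame_time_s"]))
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            if "frames" not in fh:
                raise ValueError(f"{path} has no 'frames' dataset")
            ds = fh["frames"]
            missing = [a for a in _REQUIRED_ATTRS if a not in ds.attrs]
            if missing:
                raise ValueError(
                    f"{path} lacks required metadata attributes: {missing}")
            return CameraVideo(ds[...], float(ds.attrs["pixel_size_nm"]),
                               float(ds.attrs["frame_time_s"]))
    raise ValueError(f"unsupported video format: {path.suffix}")


def frame_average(video: CameraVideo, navg: int = 5) -> CameraVideo:
    """Block mean over ``navg`` consecutive frames; frame_time scales up.

    A trailing remainder of fewer than ``navg`` frames is dropped with a
    warning.
    """
    if navg < 1:
        raise ValueError("navg must be >= 1")
    if navg == 1:
        return CameraVideo(video.frames.copy(), video.pixel_size_nm,
                           video.frame_time_s)
    n = video.n_frames
    n_keep = (n // navg) * navg
    if n_keep < n:
        warnings.warn(f"dropping {n - n_keep} trailing frames not filling an "
                      f"average block", stacklevel=2)
    f = video.frames[:n_keep].reshape(n // navg, navg, *video.frames.shape[1:])
    return CameraVideo(f.mean(axis=1), video.pixel_size_nm,
                       video.frame_time_s * navg)


def pixel_bin(video: CameraVideo, nbin: int) -> CameraVideo:
    """Block mean over nbin x nbin pixels; pixel_size scales up."""
    if nbin < 1:
        raise ValueError("nbin must be >= 1")
    if nbin == 1:
        return CameraVideo(video.frames.copy(), video.pixel_size_nm,
                           video.frame_time_s)
    n, h, w = video.frames.shape
    h_keep, w_keep = (h // nbin) * nbin, (w // nbin) * nbin
    if h_keep < h or w_keep < w:
        warnings.warn("dropping trailing rows/cols not filling a bin",
                      stacklevel=2)
    f = video.frames[:, :h_keep, :w_keep]
    f = f.reshape(n, h_keep // nbin, nbin, w_keep // nbin, nbin).mean(axis=(2, 4))
    return CameraVideo(f, video.pixel_size_nm * nbin, video.frame_time_s)


def write_manifest(path, config: dict, extra: dict | None = None) -> None:
    """Record run parameters (and provenance extras) as JSON."""
    payload = {"config": config}
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
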