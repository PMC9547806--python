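"""Reading and writing image stacks, tables and run manifests.

Image stacks go to OME-TIFF via :mod:`tifffile` with axes ``TCYX`` and
physical pixel size in the OME metadata.  Because frame times and channel
names survive OME round-trips only partially across readers, a JSON sidecar
(``<file>.json``) carrying ``pixel_size_um``, ``frame_times_s`` and
``channel_names`` is always written next to the TIFF and preferred when
loading.  Tables are plain CSV.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import uuid
from pathlib import Path

import numpy as np
import tifffile

from .errors import InvalidArgumentError
from .synth import ImageStack


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def save_image_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write an :class:`ImageStack` as OME-TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # content-derived UUID keeps repeated writes byte-identical (reproducibility)
    digest = hashlib.sha256(
        stack.data.tobytes()
        + stack.frame_times.tobytes()
        + ",".join(stack.channel_names).encode()
    ).digest()
    content_uuid = str(uuid.UUID(bytes=digest[:16], version=4))
    tifffile.imwrite(
        path,
        stack.data,
        ome=True,
        metadata={
            "UUID": f"urn:uuid:{content_uuid}",
            "axes": "TCYX",
            "PhysicalSizeX": stack.pixel_size,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.pixel_size,
            "PhysicalSizeYUnit": "µm",
            "Channel": {"Name": list(stack.channel_names)},
        },
    )
    _sidecar(path).write_text(
        json.dumps(
            {
                "pixel_size_um": stack.pixel_size,
                "frame_times_s": stack.frame_times.tolist(),
                "channel_names": list(stack.channel_names),
            }
        )
    )
    return path


def load_image_stack(path: str | Path, pixel_size: float | None = None) -> ImageStack:
    """Load a TIFF/OME-TIFF written by :func:`save_image_stack` or elsewhere.

    Metadata resolution order: JSON sidecar, then OME metadata, then the
    explicit ``pixel_size`` argument (required if neither source carries it).
    Arrays with fewer than four axes are promoted to ``TCYX``.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        ome_px, ome_channels, ome_sizes = None, None, None
        if tif.ome_metadata:
            try:
                meta = tifffile.xml2dict(tif.ome_metadata)["OME"]["Image"]
                if isinstance(meta, list):
                    meta = meta[0]
                pixels = meta["Pixels"]
                ome_px = float(pixels.get("PhysicalSizeX")) if pixels.get("PhysicalSizeX") \
                    else None
                if all(pixels.get(k) for k in ("SizeT", "SizeC", "SizeY", "SizeX")):
                    ome_sizes = tuple(int(pixels[k])
                                      for k in ("SizeT", "SizeC", "SizeY", "SizeX"))
                ch = pixels.get("Channel")
                if isinstance(ch, dict):
                    ch = [ch]
                if ch:
                    ome_channels = [c.get("Name", f"ch{i}") for i, c in enumerate(ch)]
            except (KeyError, TypeError, ValueError):
                pass

    side = _sidecar(path)
    meta = json.loads(side.read_text()) if side.exists() else {}

    # readers squeeze singleton T/C axes; restore TCYX from the metadata
    if "frame_times_s" in meta and "channel_names" in meta:
        shape = (len(meta["frame_times_s"]), len(meta["channel_names"]),
                 data.shape[-2], data.shape[-1])
        if int(np.prod(shape)) == data.size:
            data = data.reshape(shape)
    elif ome_sizes and int(np.prod(ome_sizes)) == data.size:
        data = data.reshape(ome_sizes)
    if data.ndim == 2:
        data = data[None, None]
    elif data.ndim == 3:
        data = data[:, None]
    elif data.ndim != 4:
        raise InvalidArgumentError(f"cannot interpret TIFF with shape {data.shape}")

    px = meta.get("pixel_size_um") or ome_px or pixel_size
    if not px:
        raise InvalidArgumentError("no pixel size in metadata; pass pixel_size explicitly")
    frame_times = np.asarray(meta.get("frame_times_s", np.arange(data.shape[0])), dtype=float)
    channels = meta.get("channel_names") or ome_channels or \
        [f"ch{i}" for i in range(data.shape[1])]
    return ImageStack(data=data, frame_times=frame_times,
                      channel_names=list(channels), pixel_size=float(px))


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_manifest(path: str | Path, config: dict, outputs: list[str | Path],
                   seed: int | None = None) -> Path:
    """Write a run manifest: resolved config, seed, output checksums, version.

    Written atomically (temp file + rename) at the end of a run so a partial
    run never leaves a valid-looking manifest behind.
    """
    from . import __version__

    path = Path(path)
    manifest = {
        "package": "clusterlab",
        "version": __version__,
        "timestamp_utc": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "seed": seed,
        "config": _jsonable(config),
        "outputs": [
            {"path": str(Path(p)), "sha256": sha256_of(p)} for p in outputs
            if Path(p).exists()
        ],
    }
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    tmp.replace(path)
    return path
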