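"""Reading and writing the pipeline's file formats.

Trace bundles travel as long-format CSV with columns
``time_s, cell_id, roi, channel, intensity`` where ``roi`` is one of
mother, bud, control1..control5, background.  Normalized traces add a
``units=percent`` column.  Spot images are single-page grayscale TIFFs
with a JSON sidecar holding the masks and ground truth.  Run
configurations are YAML/JSON mappings with a mandatory ``seed``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .quant import NormalizedBundle
from .simkit import SpotImage, TraceBundle

__all__ = [
    "bundle_to_frame",
    "bundles_to_frame",
    "frame_to_bundles",
    "write_bundles_csv",
    "read_bundles_csv",
    "normalized_to_frame",
    "write_spot_image",
    "read_spot_image",
    "load_config",
]

_CONTROL_ROIS = tuple(f"control{i}" for i in range(1, 6))


def bundle_to_frame(bundle: TraceBundle) -> pd.DataFrame:
    """One bundle to long-format rows."""
    rows = []
    traces = {"mother": bundle.mother, "bud": bundle.bud, "background": bundle.background}
    for i, name in enumerate(_CONTROL_ROIS):
        traces[name] = bundle.controls[i]
    for roi, values in traces.items():
        rows.append(
            pd.DataFrame(
                {
                    "time_s": bundle.times,
                    "cell_id": bundle.cell_id,
                    "roi": roi,
                    "channel": bundle.channel,
                    "intensity": values,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def bundles_to_frame(bundles: Sequence[TraceBundle]) -> pd.DataFrame:
    return pd.concat([bundle_to_frame(b) for b in bundles], ignore_index=True)


def frame_to_bundles(frame: pd.DataFrame) -> list[TraceBundle]:
    """Rebuild bundles from long-format rows (one per cell_id x channel)."""
    required = {"time_s", "cell_id", "roi", "channel", "intensity"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    bundles = []
    for (cell_id, channel), group in frame.groupby(["cell_id", "channel"], sort=True):
        pivot = group.pivot_table(
            index="time_s", columns="roi", values="intensity", aggfunc="first"
        ).sort_index()
        for roi in ("mother", "bud", "background", *_CONTROL_ROIS):
            if roi not in pivot.columns:
                raise ValueError(f"cell {cell_id!r}: missing roi {roi!r}")
        bundles.append(
            TraceBundle(
                times=pivot.index.to_numpy(dtype=float),
                mother=pivot["mother"].to_numpy(),
                bud=pivot["bud"].to_numpy(),
                controls=np.vstack([pivot[c].to_numpy() for c in _CONTROL_ROIS]),
                background=pivot["background"].to_numpy(),
                channel=str(channel),
                cell_id=str(cell_id),
            )
        )
    return bundles


def write_bundles_csv(bundles: Sequence[TraceBundle], path: str | Path, header_comment: str | None = None) -> None:
    path = Path(path)
    frame = bundles_to_frame(bundles)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, index=False)


def read_bundles_csv(path: str | Path) -> list[TraceBundle]:
    frame = pd.read_csv(path, comment="#")
    return frame_to_bundles(frame)


def normalized_to_frame(bundles: Sequence[NormalizedBundle]) -> pd.DataFrame:
    """Normalized percent traces in the same long schema plus a units column."""
    rows = []
    for nb in bundles:
        for roi in ("mother", "bud"):
            rows.append(
                pd.DataFrame(
                    {
                        "time_s": nb.times,
                        "cell_id": nb.cell_id,
                        "roi": roi,
                        "channel": "green",
                        "intensity": nb.roi(roi),
                        "units": "percent",
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def write_spot_image(image: SpotImage, tiff_path: str | Path, sidecar_path: str | Path | None = None) -> None:
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, image.pixels.astype(np.float32))
    sidecar = Path(sidecar_path) if sidecar_path else tiff_path.with_suffix(".json")
    payload = {
        "mother_mask": image.mother_mask.astype(int).tolist(),
        "bud_mask": image.bud_mask.astype(int).tolist(),
        "psf_sigma": image.psf_sigma,
        "true_spots": [[int(y), int(x), str(c)] for y, x, c in image.true_spots],
    }
    sidecar.write_text(json.dumps(payload))


def read_spot_image(tiff_path: str | Path, sidecar_path: str | Path | None = None) -> SpotImage:
    tiff_path = Path(tiff_path)
    pixels = tifffile.imread(tiff_path).astype(float)
    sidecar = Path(sidecar_path) if sidecar_path else tiff_path.with_suffix(".json")
    payload = json.loads(sidecar.read_text())
    return SpotImage(
        pixels=pixels,
        mother_mask=np.asarray(payload["mother_mask"], dtype=bool),
        bud_mask=np.asarray(payload["bud_mask"], dtype=bool),
        psf_sigma=float(payload.get("psf_sigma", 1.5)),
        true_spots=[(int(y), int(x), str(c)) for y, x, c in payload.get("true_spots", [])],
    )


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON run configuration; a ``seed`` field is mandatory."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    if "seed" not in data:
        raise ValueError("config must define a seed")
    return data
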