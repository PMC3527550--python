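"""File-format plumbing: TIFF wells, plate maps, FASTA + region tables.

Images are written one 16-bit grayscale TIFF per channel per well,
``<plate>_<well>_<channel>.tif``.  Tabular formats are plain CSV/TSV;
ground-truth sidecars are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .imagequant import ImageField
from .seedscan import TranscriptModel


def write_well_images(field: ImageField, out_dir: str | Path, plate: str, well: str) -> list:
    """One 16-bit TIFF per channel: ``<plate>_<well>_<channel>.tif``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for channel, image in field.channels.items():
        path = out_dir / f"{plate}_{well}_{channel}.tif"
        tifffile.imwrite(path, np.asarray(image, dtype=np.uint16))
        paths.append(path)
    return paths


def read_well_images(image_dir: str | Path, plate: str, well: str) -> ImageField:
    """Load all channels of one well back into an ImageField."""
    image_dir = Path(image_dir)
    channels = {}
    for path in sorted(image_dir.glob(f"{plate}_{well}_*.tif")):
        channel = path.stem.split("_")[-1]
        channels[channel] = tifffile.imread(path)
    if not channels:
        raise FileNotFoundError(f"no images for {plate}/{well} in {image_dir}")
    return ImageField(channels, source_id=f"{plate}_{well}")


def read_fasta_models(
    fasta_path: str | Path, regions_path: str | Path
) -> list[TranscriptModel]:
    """Assemble TranscriptModels from a FASTA and a region TSV.

    The region table has columns ``transcript_id, region, start, end``
    (0-based half-open).  DNA sequences (with T) are accepted; they are
    mapped to RNA internally.
    """
    from Bio import SeqIO

    regions = pd.read_csv(regions_path, sep="\t")
    by_tx = {
        tid: {r.region: (int(r.start), int(r.end)) for r in grp.itertuples()}
        for tid, grp in regions.groupby("transcript_id")
    }
    models = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        models.append(
            TranscriptModel(rec.id, str(rec.seq), by_tx.get(rec.id, {}), gene=rec.id)
        )
    return models


def write_ground_truth(truth: dict | pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(truth, pd.DataFrame):
        truth = truth.to_dict(orient="records")
    path.write_text(json.dumps(truth, indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def cells_frame(records, well: str = "") -> pd.DataFrame:
    """Per-cell CSV layout from CellRecord objects."""
    return pd.DataFrame(
        [
            {
                "well": well,
                "label": c.label,
                "area": c.nucleus_area,
                "centroid_r": c.centroid[0],
                "centroid_c": c.centroid[1],
                "ligand_intensity": c.ligand_intensity,
                "marker_intensity": c.marker_intensity,
            }
            for c in records
        ]
    )
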