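"""Synthetic annotated transcripts with planted seed-binding sites.

Background sequence is generated free of the 6-mer site core (CACUUU for
the miR-17 family) by resampling any accidental occurrence, so planted
site counts are exact by construction: a scan of the emitted sequence
finds the planted coordinates and nothing else (verified at generation
time; the transcript is regenerated in the rare case a planted junction
recreates the core).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..seedscan import TranscriptModel, scan_sequence

RNA_BASES = np.array(list("ACGU"))
DEFAULT_MOTIF = "GCACUUU"


@dataclass
class PlantedSites:
    transcript: str
    region: str  # utr5 | cds | utr3
    count: int
    allow_pos1_mismatch: bool = False


@dataclass
class TranscriptomeSpec:
    n_transcripts: int = 10
    region_length_ranges: dict = field(
        default_factory=lambda: {"utr5": (80, 200), "cds": (300, 900), "utr3": (200, 800)}
    )
    planted_sites: list = field(default_factory=list)
    alphabet: str = "RNA"  # RNA | DNA (FASTA output uses T for DNA)
    motif: str = DEFAULT_MOTIF
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.alphabet not in ("RNA", "DNA"):
            raise ValueError("alphabet must be RNA or DNA")
        for ps in self.planted_sites:
            lo, hi = self.region_length_ranges[ps.region]
            if ps.count * (len(self.motif) + 2) > lo:
                raise ValueError(
                    f"{ps.count} sites cannot be guaranteed to fit a "
                    f"{ps.region} of minimum length {lo}"
                )


def _random_background(rng, length: int, core: str) -> str:
    """Random RNA of given length containing no occurrence of ``core``."""
    seq = list(rng.choice(RNA_BASES, size=length))
    s = "".join(seq)
    guard = 0
    while True:
        pos = s.find(core)
        if pos == -1:
            return s
        guard += 1
        if guard > 100 * length:  # pragma: no cover
            raise RuntimeError("background resampling did not converge")
        for i in range(pos, pos + len(core)):
            seq[i] = rng.choice(RNA_BASES)
        s = "".join(seq)


def _plant(rng, seq: list, region_span: tuple[int, int], count: int, motif: str, pos1_free: bool):
    """Plant ``count`` non-overlapping motif copies inside a region span.

    Returns the list of (start, site_string, pos1_mismatch) planted.
    Positions are sampled with a 1-nt clearance between sites.
    """
    start, end = region_span
    usable = end - start - len(motif)
    if usable < 0 or (count and usable // (len(motif) + 1) + 1 < count):
        raise ValueError("region too short for requested sites")
    planted = []
    taken: list[tuple[int, int]] = []
    guard = 0
    while len(planted) < count:
        guard += 1
        if guard > 10000:  # pragma: no cover
            raise RuntimeError("site placement did not converge")
        pos = int(rng.integers(start, end - len(motif) + 1))
        if any(pos < t_end + 1 and t_start - len(motif) - 1 < pos for t_start, t_end in taken):
            continue
        site = motif
        mismatch = False
        if pos1_free:
            alt = [b for b in "ACGU" if b != motif[0]]
            site = str(rng.choice(alt)) + motif[1:]
            mismatch = True
        seq[pos : pos + len(motif)] = list(site)
        taken.append((pos, pos + len(motif)))
        planted.append((pos, site, mismatch))
    planted.sort()
    return planted


def make_transcriptome(
    spec: TranscriptomeSpec,
) -> tuple[list, pd.DataFrame, pd.DataFrame]:
    """Generate transcripts, region table and planted-site ground truth.

    Returns ``(models, regions, truth)`` where ``models`` are
    :class:`~mirtraffic.seedscan.TranscriptModel` objects, ``regions`` is
    the tabular annotation (transcript_id, region, start, end; 0-based
    half-open) and ``truth`` records every planted site coordinate.
    """
    rng = np.random.default_rng(spec.rng_seed)
    core = spec.motif[1:]
    by_tx: dict[str, list[PlantedSites]] = {}
    for ps in spec.planted_sites:
        by_tx.setdefault(ps.transcript, []).append(ps)

    models, region_rows, truth_rows = [], [], []
    names = [f"TX{i + 1:04d}" for i in range(spec.n_transcripts)]
    extra = [t for t in by_tx if t not in names]
    names += extra  # explicitly named planted transcripts beyond n_transcripts
    for name in names:
        for _attempt in range(50):
            lengths = {}
            for region, (lo, hi) in spec.region_length_ranges.items():
                n = int(rng.integers(lo, hi + 1))
                if region == "cds":
                    n -= n % 3
                lengths[region] = n
            total = sum(lengths.values())
            seq = list(_random_background(rng, total, core))
            spans, offset = {}, 0
            for region in ("utr5", "cds", "utr3"):
                if region in lengths:
                    spans[region] = (offset, offset + lengths[region])
                    offset += lengths[region]
            planted_here = []
            for ps in by_tx.get(name, []):
                for pos, site, mm in _plant(
                    rng, seq, spans[ps.region], ps.count, spec.motif, ps.allow_pos1_mismatch
                ):
                    planted_here.append((pos, ps.region, site, mm))
            sequence = "".join(seq)
            # construction check: the scan must find exactly the planted sites
            found = {s for s, _, _ in scan_sequence(sequence, spec.motif, "pos1_tolerant")}
            if found == {p for p, _, _, _ in planted_here}:
                break
        else:  # pragma: no cover
            raise RuntimeError(f"could not build clean transcript {name}")
        models.append(TranscriptModel(name, sequence, spans, gene=name))
        for region, (s, e) in spans.items():
            region_rows.append({"transcript_id": name, "region": region, "start": s, "end": e})
        for pos, region, site, mm in sorted(planted_here):
            truth_rows.append(
                {
                    "transcript_id": name,
                    "start": pos,
                    "region": region,
                    "site": site,
                    "pos1_mismatch": mm,
                }
            )
    regions = pd.DataFrame(region_rows, columns=["transcript_id", "region", "start", "end"])
    truth = pd.DataFrame(
        truth_rows, columns=["transcript_id", "start", "region", "site", "pos1_mismatch"]
    )
    return models, regions, truth


def write_fasta(models, path: str | Path, alphabet: str = "RNA") -> None:
    """Write transcripts as FASTA (T instead of U when alphabet='DNA')."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = []
    for m in models:
        seq = m.sequence if alphabet == "RNA" else m.sequence.replace("U", "T")
        records.append(SeqRecord(Seq(seq), id=m.transcript_id, description=""))
    seqio_write(records, str(path), "fasta")
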