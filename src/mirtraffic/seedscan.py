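"""miRNA seed-site scanning of annotated transcripts.

A miRNA recognises its targets primarily through its *seed*, nucleotides
2-8 of the mature miRNA.  The mRNA-side seed-binding site is the reverse
complement of the seed, read 5'->3'.  For the miR-17 seed family
(seed 5'-AAAGUGC-3') that site is 5'-GCACUUU-3'.

Two scanning policies are supported:

``exact``
    all seven positions of the site motif must match.
``pos1_tolerant`` (default)
    position 1 of the motif is free; positions 2-7 (the CACUUU core for
    the miR-17 family) must match exactly.  This encodes the rule that
    no mismatches are tolerated inside the 6-mer core while the base
    pairing opposite miRNA position 8 may be imperfect.

Sites are located by direct string scanning: for a fixed 7-mer with a
single constrained-mismatch rule an exhaustive scan is exact, trivially
reproducible and faster than any heuristic alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import pandas as pd

RNA_ALPHABET = frozenset("ACGU")
REGIONS = ("utr5", "cds", "utr3")

_COMPLEMENT = str.maketrans("ACGU", "UGCA")

Policy = Literal["exact", "pos1_tolerant"]


def _to_rna(seq: str) -> str:
    """Uppercase and map DNA thymine to uracil."""
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class SeedDef:
    """A miRNA seed: the 7 nt at positions 2-8 of the mature miRNA, 5'->3'."""

    mirna: str
    seed: str

    def __post_init__(self) -> None:
        seed = _to_rna(self.seed)
        object.__setattr__(self, "seed", seed)
        if len(seed) != 7:
            raise ValueError(f"seed must be 7 nt, got {len(seed)!r}")
        if not set(seed) <= RNA_ALPHABET:
            raise ValueError(f"seed contains non-RNA characters: {seed!r}")


@dataclass
class TranscriptModel:
    """An annotated mRNA: sequence plus 0-based half-open region intervals.

    Regions must be disjoint and ordered 5'UTR < CDS < 3'UTR; any of them
    may be absent (empty interval).  ``gene`` groups transcript variants of
    one gene; all variants of a gene are scanned.
    """

    transcript_id: str
    sequence: str
    regions: dict  # region name -> (start, end), 0-based half-open
    gene: str = ""

    def __post_init__(self) -> None:
        self.sequence = _to_rna(self.sequence)
        prev_end = 0
        for name in REGIONS:
            if name not in self.regions:
                continue
            start, end = self.regions[name]
            if not (0 <= start <= end <= len(self.sequence)):
                raise ValueError(f"region {name} out of bounds: {start, end}")
            if start < prev_end:
                raise ValueError(f"region {name} overlaps/unordered")
            prev_end = end

    def region_of(self, offset: int) -> str:
        """Region containing a site *start* offset; 'unassigned' if none."""
        for name in REGIONS:
            if name in self.regions:
                start, end = self.regions[name]
                if start <= offset < end:
                    return name
        return "unassigned"


@dataclass(frozen=True)
class SeedSite:
    transcript_id: str
    start: int
    region: str
    matched: str
    pos1_mismatch: bool


def target_site_motif(seed: SeedDef | str) -> str:
    """mRNA-side site for a seed: its reverse complement, 5'->3'.

    >>> target_site_motif(SeedDef("miR-17", "AAAGUGC"))
    'GCACUUU'
    """
    seq = seed.seed if isinstance(seed, SeedDef) else _to_rna(seed)
    if not set(seq) <= RNA_ALPHABET:
        raise ValueError(f"non-RNA characters in seed: {seq!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def scan_sequence(
    sequence: str,
    motif: str,
    policy: Policy = "pos1_tolerant",
) -> list[tuple[int, str, bool]]:
    """All (overlapping) occurrences of a 7-nt site motif in a sequence.

    Returns ``(offset, matched_string, pos1_mismatch)`` tuples.  Under
    ``pos1_tolerant`` the motif's first position may be any base; the match
    is then flagged ``pos1_mismatch=True`` when that base differs from the
    motif.  T is treated as U on both sides.
    """
    motif = _to_rna(motif)
    if len(motif) != 7:
        raise ValueError(f"site motif must be 7 nt, got {len(motif)}")
    if policy not in ("exact", "pos1_tolerant"):
        raise ValueError(f"unknown policy {policy!r}")
    seq = _to_rna(sequence)
    core = motif[1:]
    hits: list[tuple[int, str, bool]] = []
    # scan for the 6-mer core; check position 1 according to policy
    pos = seq.find(core, 1)
    while pos != -1:
        start = pos - 1
        first = seq[start]
        if first == motif[0]:
            hits.append((start, seq[start : start + 7], False))
        elif policy == "pos1_tolerant":
            hits.append((start, seq[start : start + 7], True))
        pos = seq.find(core, pos + 1)
    return hits


@dataclass
class RegionCounts:
    """Per-region seed-site tallies for one transcript."""

    transcript_id: str
    gene: str
    counts: dict
    sites: list = field(default_factory=list)

    def total(self) -> int:
        return sum(self.counts.values())


def count_by_region(
    model: TranscriptModel,
    motif: str,
    policy: Policy = "pos1_tolerant",
) -> RegionCounts:
    """Scan one transcript and tally sites per annotated region.

    A site is assigned to the region containing its start offset (a site
    straddling the CDS/3'UTR boundary counts toward the CDS).  Sites that
    start outside every annotated region land in an 'unassigned' bucket.
    """
    counts = {name: 0 for name in REGIONS}
    counts["unassigned"] = 0
    sites = []
    for start, matched, pos1 in scan_sequence(model.sequence, motif, policy):
        region = model.region_of(start)
        counts[region] += 1
        sites.append(SeedSite(model.transcript_id, start, region, matched, pos1))
    return RegionCounts(model.transcript_id, model.gene, counts, sites)


def family_presence_matrix(
    models: Iterable[TranscriptModel],
    seeds: Sequence[SeedDef],
    policy: Policy = "pos1_tolerant",
    utr3_only: bool = False,
) -> pd.DataFrame:
    """Gene x miRNA presence/absence of seed-binding sites.

    A gene is 'present' for a miRNA when at least one transcript variant
    carries at least one site (in the 3'UTR only if ``utr3_only``).
    miRNAs sharing a seed necessarily produce identical columns.
    """
    models = list(models)
    genes = sorted({m.gene or m.transcript_id for m in models})
    mat = pd.DataFrame(False, index=genes, columns=[s.mirna for s in seeds])
    motif_cache: dict[str, str] = {}
    for seed in seeds:
        motif = motif_cache.setdefault(seed.seed, target_site_motif(seed))
        for model in models:
            gene = model.gene or model.transcript_id
            if mat.at[gene, seed.mirna]:
                continue
            rc = count_by_region(model, motif, policy)
            n = rc.counts["utr3"] if utr3_only else rc.total()
            if n > 0:
                mat.at[gene, seed.mirna] = True
    return mat


def sites_table(counts: Iterable[RegionCounts]) -> pd.DataFrame:
    """Flatten RegionCounts into a tidy sites DataFrame."""
    rows = [
        {
            "transcript": s.transcript_id,
            "start": s.start,
            "region": s.region,
            "matched": s.matched,
            "pos1_mismatch": s.pos1_mismatch,
        }
        for rc in counts
        for s in rc.sites
    ]
    return pd.DataFrame(rows, columns=["transcript", "start", "region", "matched", "pos1_mismatch"])
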