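"""Published reference values bundled with the package.

``TABLE1`` is the published hit table of the miR-17 over-expression
profiling experiment: the transcripts whose expression changed at least
1.8-fold 12/24/48 h after transfection, with their signed linear fold
changes and the number of miR-17 seed-binding sites per transcript
region.  It serves as input to worked examples (e.g. re-applying the
fold-change filter) and as an external consistency check for the
expression pipeline's conventions.

``SEED_FAMILIES`` lists the seed sequences (miRNA positions 2-8, 5'->3')
of the miR-17-92, miR-106a-363 and miR-106b-25 cluster members grouped by
shared seed; miRNAs sharing a seed hit identical target sites.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .seedscan import SeedDef


def _load_table1() -> pd.DataFrame:
    with resources.files("mirtraffic.data").joinpath("table1_fold_changes.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


TABLE1: pd.DataFrame = _load_table1()

MIR17_SEED = SeedDef("miR-17", "AAAGUGC")

#: seed -> member miRNAs of the three paralogous clusters
SEED_FAMILIES: dict[str, tuple[str, ...]] = {
    "AAAGUGC": ("miR-17", "miR-20a", "miR-20b", "miR-93", "miR-106a", "miR-106b"),
    "AAGGUGC": ("miR-18a", "miR-18b"),
    "AUUGCAC": ("miR-92a", "miR-25", "miR-363"),
    "GUGCAAA": ("miR-19a", "miR-19b"),
    "AAAGCUG": ("miR-320a",),
}


def table1_records() -> list:
    """TABLE1 rows as :class:`~mirtraffic.expression.FoldChangeRecord`."""
    from .expression import FoldChangeRecord

    return [
        FoldChangeRecord(r.gene, int(r.timepoint), float(r.fold_change), None)
        for r in TABLE1.itertuples()
    ]
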