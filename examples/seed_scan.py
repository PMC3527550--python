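"""Scan transcripts for miR-17 seed-binding sites and tally them per region.

Builds a small synthetic transcriptome with known planted sites (one
3'UTR site, three CDS sites, one 5'UTR site) and scans it with the
miR-17 family motif.  The printed counts should equal the planted layout,
and miRNAs sharing a seed must light up the same genes.
"""

from mirtraffic.reference import SEED_FAMILIES
from mirtraffic.seedscan import SeedDef, count_by_region, family_presence_matrix, target_site_motif
from mirtraffic.synthgen import PlantedSites, TranscriptomeSpec, make_transcriptome

seed = SeedDef("miR-17", "AAAGUGC")
motif = target_site_motif(seed)
print(f"miR-17 seed {seed.seed} -> mRNA-side site motif {motif}")

spec = TranscriptomeSpec(
    n_transcripts=3,
    planted_sites=[
        PlantedSites("TX0001", "utr3", 1),
        PlantedSites("TX0002", "cds", 3),
        PlantedSites("TX0003", "utr5", 1),
    ],
    rng_seed=4,
)
models, regions, truth = make_transcriptome(spec)

print("\nper-region site counts (planted: TX0001 1x3'UTR, TX0002 3xCDS, TX0003 1x5'UTR):")
for m in models:
    rc = count_by_region(m, motif, "pos1_tolerant")
    print(f"  {m.transcript_id}: 5'UTR={rc.counts['utr5']}  CDS={rc.counts['cds']}  3'UTR={rc.counts['utr3']}")

family = SEED_FAMILIES["AAAGUGC"]
seeds = [SeedDef(name, "AAAGUGC") for name in family]
mat = family_presence_matrix(models, seeds)
print("\ngene x miRNA presence for the miR-17 seed family (True = site present):")
print(mat)
same = all((mat[m] == mat[family[0]]).all() for m in family[1:])
print(
    f"\nAll {len(family)} family members share the seed, so their presence"
    f" columns are identical: {same}.  (The generated background is kept"
    " free of the miR-17 site core; unrelated seeds may still match random"
    " background by chance and are not compared here.)"
)
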