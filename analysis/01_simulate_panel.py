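#!/usr/bin/env python
"""Generate the synthetic RI panel used by the downstream analyses.

Builds the packaged study-condition preset (64 strains x 6 mice, one
planted major lick-rate locus on chromosome 1 plus a weaker secondary
locus on chromosome 10) and writes the raw artifacts: a GeneNetwork-style
.geno file and sessions/events CSVs of simulated lickometer streams.

Bulk data land in scratch/analysis_data/ (regenerated on demand); the
per-strain genotype summary goes to results/.
"""

from dataclasses import replace
from pathlib import Path

from lickqtl.genome import write_geno
from lickqtl.simulate import QTLSpec, paper_matched, simulate_panel

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "analysis_data"

SEED = 1
SECONDARY_MARKER = "c10m07"  # weaker locus, 3.3 ms per D allele
SECONDARY_EFFECT = 3.3


def main() -> None:
    gmap, cfg = paper_matched(seed=SEED)
    cfg = replace(cfg, qtls=cfg.qtls + (QTLSpec(SECONDARY_MARKER,
                                                -SECONDARY_EFFECT),))
    geno, pheno, sessions, events = simulate_panel(cfg, gmap)

    DATA.mkdir(parents=True, exist_ok=True)
    write_geno(geno, DATA / "panel.geno")
    sessions.to_csv(DATA / "sessions.csv", index=False)
    events.to_csv(DATA / "events.csv", index=False)

    d_frac = (geno.codes == "D").mean()
    print(f"panel: {geno.n_strains} strains, {len(gmap.table)} markers, "
          f"D-allele fraction {d_frac:.3f}")
    print(f"planted loci: {[q.marker_name for q in cfg.qtls]} "
          f"(per-D-allele effects {[q.per_allele_effect for q in cfg.qtls]} ms)")
    print(f"{len(sessions)} sessions / {len(events)} lick events -> {DATA}")


if __name__ == "__main__":
    main()
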