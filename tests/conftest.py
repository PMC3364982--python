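import numpy as np
import pandas as pd
import pytest

from lickqtl.genome import GenoMap, GenotypeMatrix, uniform_map
from lickqtl.simulate import paper_matched, simulate_ri_genotypes


@pytest.fixture(scope="session")
def tiny_map() -> GenoMap:
    """Two chromosomes, three markers each, 10 cM spacing."""
    return uniform_map(n_chrom=2, markers_per_chrom=3, spacing_cM=10.0)


@pytest.fixture(scope="session")
def preset_panel():
    """One paper_matched panel: (map, config, genotypes)."""
    gmap, cfg = paper_matched(seed=42)
    geno = simulate_ri_genotypes(gmap, cfg.n_strains, cfg.seed)
    return gmap, cfg, geno


def make_geno(codes, chrom=None, cM=None, strains=None) -> GenotypeMatrix:
    """Hand-built genotype matrix from a list of per-strain code strings."""
    codes = np.array([list(row) for row in codes])
    n_strains, n_markers = codes.shape
    chrom = chrom or ["1"] * n_markers
    cM = cM if cM is not None else [10.0 * j for j in range(n_markers)]
    table = pd.DataFrame({
        "name": [f"m{j}" for j in range(n_markers)],
        "chrom": chrom, "cM": cM, "Mb": [2.0 * c for c in cM],
    })
    strains = strains or [f"S{i}" for i in range(n_strains)]
    return GenotypeMatrix(strains=strains, gmap=GenoMap(table), codes=codes)
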