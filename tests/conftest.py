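import numpy as np
import pandas as pd
import pytest

from rohdep.io import MISSING, GenotypeMatrix


def make_snps(n_snps, chromosome=1, spacing_bp=25_000, rate_cm_per_mb=1.28, start=1):
    bp = start + spacing_bp * np.arange(n_snps)
    return pd.DataFrame(
        {
            "snp_id": [f"c{chromosome}s{j}" for j in range(n_snps)],
            "chromosome": chromosome,
            "bp": bp,
            "cM": bp / 1e6 * rate_cm_per_mb,
            "alleleA": "A",
            "alleleB": "B",
        }
    )


def random_genotypes(rng, n_ind=10, n_snps=50, missing_rate=0.02, chromosomes=(1,)):
    """Random HWE-ish genotype fixture spread over chromosomes."""
    frames = []
    per = n_snps // len(chromosomes)
    for c in chromosomes:
        frames.append(make_snps(per, chromosome=c))
    snps = pd.concat(frames, ignore_index=True)
    p = rng.uniform(0.05, 0.95, size=len(snps))
    codes = (rng.random((n_ind, len(snps))) < p).astype(np.int8) + (
        rng.random((n_ind, len(snps))) < p
    ).astype(np.int8)
    if missing_rate > 0:
        codes[rng.random(codes.shape) < missing_rate] = MISSING
    ids = [f"ind{i}" for i in range(n_ind)]
    return GenotypeMatrix(ids, snps, codes)


def roh_prone_genotypes(rng, n_ind=20, n_snps=400, chromosome=1, spacing_bp=25_000):
    """Genotypes with alternating IBD-like homozygous blocks, so the ROH
    caller has realistic segments, gaps, heterozygotes and missing calls
    to chew on."""
    snps = make_snps(n_snps, chromosome=chromosome, spacing_bp=spacing_bp)
    p = rng.uniform(0.2, 0.8, size=n_snps)
    codes = np.empty((n_ind, n_snps), dtype=np.int8)
    for i in range(n_ind):
        j = 0
        while j < n_snps:
            block = int(rng.integers(20, 120))
            end = min(n_snps, j + block)
            if rng.random() < 0.5:  # homozygous (IBD-like) block
                hap = (rng.random(end - j) < p[j:end]).astype(np.int8)
                codes[i, j:end] = 2 * hap
            else:
                a = (rng.random(end - j) < p[j:end]).astype(np.int8)
                b = (rng.random(end - j) < p[j:end]).astype(np.int8)
                codes[i, j:end] = a + b
            j = end
        # sprinkle noise
        noise = rng.random(n_snps)
        codes[i, noise < 0.01] = 1
        codes[i, (noise >= 0.01) & (noise < 0.02)] = MISSING
    return GenotypeMatrix([f"ind{i}" for i in range(n_ind)], snps, codes)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
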