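import math
from fractions import Fraction

import pytest

from methylmotif import SimulationConfig, simulate_study
from methylmotif.cpg_io import extract_flanks


def fisher_oracle(a: int, b: int, c: int, d: int, alternative: str) -> float:
    """Brute-force Fisher p: enumerate all 2x2 tables with the observed
    margins using exact rational point probabilities."""
    r1, c1, n = a + b, a + c, a + b + c + d
    if n == 0:
        return 1.0
    denom = math.comb(n, c1)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    weights = {
        x: Fraction(math.comb(r1, x) * math.comb(n - r1, c1 - x), denom)
        for x in range(lo, hi + 1)
    }
    if alternative == "greater":
        return float(sum(w for x, w in weights.items() if x >= a))
    w_obs = weights[a]
    return float(sum(w for w in weights.values() if w <= w_obs))


@pytest.fixture(scope="session")
def small_study():
    """A small planted-signal study reused by annotation/pipeline tests."""
    cfg = SimulationConfig(
        seed=11, n_target=80, n_background=120, chrom_len=12000, n_chrom=2
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def small_flanks(small_study):
    study = small_study
    w = study.config.flank_w
    targets = extract_flanks(
        study.genome, study.target_sets["set1"], study.annotation, w
    )
    background = extract_flanks(study.genome, study.background, study.annotation, w)
    return targets, background
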