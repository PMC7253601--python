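import numpy as np
import pytest

import coperon as cp

# Wild-type-like rate constants: K_d = k_d/k_a = 28.1 nM.
WT_KA = 1e6
WT_KD = 0.0281


@pytest.fixture(scope="session")
def wt_params() -> cp.KineticParams:
    return cp.KineticParams(k_a=WT_KA, k_d=WT_KD, R_max=1.0)


@pytest.fixture(scope="session")
def noiseless_wt_set(wt_params) -> cp.SensorgramSet:
    return cp.simulate_set(wt_params, noise=cp.NoiseModel.noiseless(), seed=0)


@pytest.fixture(scope="session")
def noisy_wt_set(wt_params) -> cp.SensorgramSet:
    return cp.simulate_set(wt_params, noise=cp.NoiseModel(), seed=0)


# ---------------------------------------------------------------------------
# independent naive scanning oracle (deliberately separate from the package's
# tables and vectorised implementation)
# ---------------------------------------------------------------------------

ORACLE_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "K": "GT", "M": "AC", "S": "CG", "W": "AT",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
ORACLE_COMP = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "K": "M", "M": "K", "S": "S", "W": "W",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def oracle_revcomp(s: str) -> str:
    return "".join(ORACLE_COMP[c] for c in reversed(s))


def oracle_scan(seq: str, pat: str, max_mismatch: int = 0, strands: str = "both"):
    """Position-by-position reference scan; returns (start, strand, mismatches)."""
    out = []
    jobs = []
    if strands in ("both", "forward"):
        jobs.append(("+", pat))
    if strands in ("both", "reverse"):
        jobs.append(("-", oracle_revcomp(pat)))
    for strand, p in jobs:
        for i in range(len(seq) - len(p) + 1):
            mm = sum(seq[i + j] not in ORACLE_IUPAC[c] for j, c in enumerate(p))
            if mm <= max_mismatch:
                out.append((i, strand, mm))
    return sorted(out)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
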