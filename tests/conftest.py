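import numpy as np
import pytest

from paleoeve import synthsim
from paleoeve.seqsearch import ScoringMatrix


@pytest.fixture(scope="session")
def blosum45():
    return ScoringMatrix.blosum45()


@pytest.fixture(scope="session")
def host_tree():
    return synthsim.default_host_tree()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def small_template():
    return synthsim.EveTemplate(
        genes=tuple(synthsim.GeneSpec(n, l) for n, l in
                    [("POLB", 120), ("INT", 80), ("MCP", 100)]),
        tir_length=30, intergenic_length=20)


@pytest.fixture(scope="session")
def small_config():
    return synthsim.SimulationConfig(
        seed=7, flank_noncoding=400, landmark_aa_length=80,
        spacer_length=60, gamma_shape=None)


# ---------------------------------------------------------------------------
# Independent oracles (deliberately simple, unvectorised implementations)
# ---------------------------------------------------------------------------

def sw_score_bruteforce(query, subject, matrix):
    """Affine-gap local alignment score by the plain three-matrix DP."""
    from paleoeve.seqsearch import _AA_INDEX

    q = [_AA_INDEX[ord(c)] for c in query]
    s = [_AA_INDEX[ord(c)] for c in subject]
    m, n = len(q), len(s)
    NEG = float("-inf")
    oe = matrix.gap_open + matrix.gap_extend
    e = matrix.gap_extend
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - oe, E[i][j - 1] - e)
            F[i][j] = max(H[i - 1][j] - oe, F[i - 1][j] - e)
            H[i][j] = max(0.0,
                          H[i - 1][j - 1] + matrix.scores[q[i - 1], s[j - 1]],
                          E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def pdistance_bruteforce(rows):
    """Naive double-loop pairwise-deletion p-distance matrix."""
    n = len(rows)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            num = den = 0
            for a, b in zip(rows[i].upper(), rows[j].upper()):
                if a in "ACGT" and b in "ACGT":
                    den += 1
                    num += a != b
            out[i, j] = num / den if den else np.nan
    return out
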