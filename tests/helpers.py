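"""Independent oracles used by the test suite.

Everything here is written from the textbook definition of the quantity it
checks — never by calling the code path under test.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices
from scipy import stats

from bilrscreen.hmm import AA, ProfileHMM


# -- Smith-Waterman affine oracle (Gotoh, quadratic space) ------------------

def gotoh_local_score(a: str, b: str, matrix="BLOSUM62", gap_open=11.0, gap_extend=1.0):
    """Textbook local affine-gap DP; a gap of length L costs open + L*extend."""
    m = substitution_matrices.load(matrix)
    NEG = -1e30
    la, lb = len(a), len(b)
    H = np.zeros((la + 1, lb + 1))
    E = np.full((la + 1, lb + 1), NEG)  # gap in a (consume b)
    F = np.full((la + 1, lb + 1), NEG)  # gap in b (consume a)
    best = 0.0
    first = gap_open + gap_extend
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            E[i, j] = max(H[i, j - 1] - first, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - first, F[i - 1, j] - gap_extend)
            H[i, j] = max(
                0.0, H[i - 1, j - 1] + m[a[i - 1], b[j - 1]], E[i, j], F[i, j]
            )
            best = max(best, H[i, j])
    return best


# -- profile-HMM brute-force oracle ----------------------------------------

def random_small_profile(rng: np.random.Generator, k: int) -> ProfileHMM:
    """A valid random profile with Dirichlet emissions/transitions."""
    emis = rng.dirichlet(np.full(20, 0.5), size=k)
    n_t = max(k - 1, 1)
    mm = rng.dirichlet([4.0, 1.0, 1.0], size=n_t)
    im = rng.dirichlet([2.0, 1.0], size=n_t)
    dm = rng.dirichlet([2.0, 1.0], size=n_t)
    return ProfileHMM(
        match_emissions=emis,
        insert_emissions=np.full(20, 1 / 20),
        background=np.full(20, 1 / 20),
        t_mm=mm[:, 0], t_mi=mm[:, 1], t_md=mm[:, 2],
        t_im=im[:, 0], t_ii=im[:, 1],
        t_dm=dm[:, 0], t_dd=dm[:, 1],
    )


def brute_force_viterbi(profile: ProfileHMM, target: str) -> float:
    """Max score over exhaustive enumeration of all local state paths.

    Paths enter at any match state (consuming a residue), move through
    M/I/D with the model's transitions, and may exit after any match state.
    Scores accumulate sequentially (emission added after transition), the
    same float-operation order the DP uses, so agreement is exact.
    """
    msc, isc, logs = profile._score_tables()
    codes = np.array([AA.index(c) for c in target])
    L, K = codes.size, profile.n_match
    msc_x = msc[:, codes].T  # (L, K)
    isc_x = isc[codes]
    lmm, lmi, lmd = logs["mm"], logs["mi"], logs["md"]
    lim, lii = logs["im"], logs["ii"]
    ldm, ldd = logs["dm"], logs["dd"]
    best = -np.inf

    def rec(state, i, j, score):
        nonlocal best
        if state == "M":
            if score > best:
                best = score
            if i + 1 < L and j + 1 < K:
                rec("M", i + 1, j + 1, (score + lmm[j]) + msc_x[i + 1, j + 1])
            if i + 1 < L and j < K - 1:
                rec("I", i + 1, j, (score + lmi[j]) + isc_x[i + 1])
            if j + 1 < K:
                rec("D", i, j + 1, score + lmd[j])
        elif state == "I":
            if i + 1 < L and j + 1 < K:
                rec("M", i + 1, j + 1, (score + lim[j]) + msc_x[i + 1, j + 1])
            if i + 1 < L:
                rec("I", i + 1, j, (score + lii[j]) + isc_x[i + 1])
        else:  # D at column j
            if i + 1 < L and j + 1 < K:
                rec("M", i + 1, j + 1, (score + ldm[j]) + msc_x[i + 1, j + 1])
            if j + 1 < K:
                rec("D", i, j + 1, score + ldd[j])

    for i0 in range(L):
        for j0 in range(K):
            rec("M", i0, j0, msc_x[i0, j0] + 0.0)
    return best


# -- Welch t oracle ---------------------------------------------------------

def welch_oracle(a, b, alternative="greater"):
    """Closed-form Welch statistic, Welch-Satterthwaite df, Student-t tail."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    m1, m2 = a.mean(), b.mean()
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    n1, n2 = a.size, b.size
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    if alternative == "greater":
        p = stats.t.sf(t, df)
    else:
        p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(p), float(df)


# -- two-proportion chi-square oracle ---------------------------------------

def chisq_2x2_oracle(x1, n1, x2, n2, correct=False):
    """Sum (O - E)^2 / E over the 2x2 table; Yates term capped like R."""
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    yates = 0.0
    if correct:
        yates = min(0.5, abs(x1 / n1 - x2 / n2) / (1 / n1 + 1 / n2))
    stat = float(np.sum((np.abs(table - expected) - yates) ** 2 / expected))
    return stat, float(stats.chi2.sf(stat, df=1))
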