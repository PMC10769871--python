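"""Profile HMM over the BilR TIM-barrel region: build, search, classify.

The model is a Plan-7-style profile: per-column match emissions over the 20
canonical residues, insert emissions equal to the background, and
match/insert/delete transitions, scored in bits (log2 odds against the
background). Search is Smith-Waterman-style local Viterbi: free entry into
any match column and free exit from any match column, so unrelated flanking
sequence costs nothing. E-values come from a Gumbel (type-I extreme value)
fit to Viterbi scores of background-model random sequences, scaled by the
database size — the same contract a calibrated homology scanner provides.

Classification applies four filters to each hit, all of which must pass for
a non-"none" verdict:

* E-value strictly below 1e-100;
* target at least 50% of the reference protein length;
* the residues aligned to the four conserved motif match columns spell
  exactly HGDR (His-Gly-Asp-Arg, the catalytic-site motif of the bilirubin
  reductase clade);
* the target's domain architecture is exactly PF00724 (short form) or
  PF07992 + PF00724 (long form).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "AA",
    "AA_INDEX",
    "PF_TIM_BARREL",
    "PF_FLAVODOXIN",
    "ProfileHMM",
    "HmmHit",
    "BilRCall",
    "ProfileBuildError",
    "CalibrationError",
    "build_profile",
    "viterbi_search",
    "viterbi_score",
    "fit_gumbel",
    "calibrate",
    "score_to_evalue",
    "classify_bilr",
    "search",
    "scan_database",
]

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}

PF_TIM_BARREL = "PF00724"  # NADH:flavin oxidoreductase TIM-barrel domain
PF_FLAVODOXIN = "PF07992"  # pyridine nucleotide-disulphide oxidoreductase

DEFAULT_EVALUE_MAX = 1e-100
DEFAULT_MIN_LENGTH_FRACTION = 0.5
DEFAULT_MOTIF = "HGDR"


class ProfileBuildError(ValueError):
    """The alignment cannot support the requested profile."""


class CalibrationError(RuntimeError):
    """Score distribution unusable for Gumbel calibration."""


def encode_protein(seq: str) -> np.ndarray:
    try:
        return np.array([AA_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r} in protein sequence") from None


@dataclass(frozen=True)
class ProfileHMM:
    """Profile HMM with motif bookkeeping and optional Gumbel calibration.

    Transitions are indexed by source column j (0..K-2): mm/mi/md from match,
    im/ii from insert, dm/dd from delete. ``motif_columns`` are 0-based match
    column indices; ``reference_length`` is the full (ungapped) length of the
    reference protein, used by the 50%-length filter.
    """

    match_emissions: np.ndarray  # (K, 20)
    insert_emissions: np.ndarray  # (20,)
    background: np.ndarray  # (20,)
    t_mm: np.ndarray
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray
    t_dd: np.ndarray
    motif_columns: tuple[int, ...] = ()
    reference_length: int = 0
    mu: float | None = None
    lam: float | None = None
    calibration_n: int = 0

    def __post_init__(self):
        k = self.n_match
        for name in ("match_emissions", "insert_emissions", "background"):
            arr = getattr(self, name)
            s = arr.sum(axis=-1)
            if not np.allclose(s, 1.0, atol=1e-9):
                raise ValueError(f"{name} must sum to 1")
        if k > 1:
            out_m = self.t_mm + self.t_mi + self.t_md
            out_i = self.t_im + self.t_ii
            out_d = self.t_dm + self.t_dd
            for name, s in (("match", out_m), ("insert", out_i), ("delete", out_d)):
                if not np.allclose(s, 1.0, atol=1e-9):
                    raise ValueError(f"{name} transitions must sum to 1")
        if self.motif_columns:
            cols = self.motif_columns
            if len(cols) != 4 or any(not 0 <= c < k for c in cols):
                raise ValueError("motif_columns must be 4 valid match-column indices")
            if any(b - a != 1 for a, b in zip(cols, cols[1:])):
                raise ValueError("motif_columns must be consecutive")
        if self.lam is not None and self.lam <= 0:
            raise ValueError("Gumbel scale parameter lambda must be positive")

    @property
    def n_match(self) -> int:
        return self.match_emissions.shape[0]

    @property
    def is_calibrated(self) -> bool:
        return self.mu is not None and self.lam is not None

    def consensus(self) -> str:
        return "".join(AA[i] for i in np.argmax(self.match_emissions, axis=1))

    # -- bit-score tables -------------------------------------------------
    def _score_tables(self):
        msc = np.log2(self.match_emissions / self.background)
        isc = np.log2(self.insert_emissions / self.background)
        logs = {
            name: np.log2(getattr(self, "t_" + name))
            for name in ("mm", "mi", "md", "im", "ii", "dm", "dd")
        }
        return msc, isc, logs

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, np.ndarray):
                v = v.tolist()
            elif isinstance(v, tuple):
                v = list(v)
            d[f.name] = v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProfileHMM":
        kwargs = dict(d)
        for name in ("match_emissions", "insert_emissions", "background",
                     "t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd"):
            kwargs[name] = np.asarray(kwargs[name], dtype=float)
        kwargs["motif_columns"] = tuple(kwargs.get("motif_columns", ()))
        return cls(**kwargs)


@dataclass
class HmmHit:
    """Best local alignment of the profile to one target."""

    target_id: str
    score: float  # bits
    target_start: int  # 1-based inclusive
    target_end: int  # 1-based inclusive
    column_map: dict[int, str]  # match column -> residue or '-'
    evalue: float | None = None


@dataclass
class BilRCall:
    """Per-protein classification verdict with the full filter audit."""

    target_id: str
    verdict: str  # none | short | long
    evalue_pass: bool
    length_pass: bool
    motif_pass: bool
    domain_pass: bool
    observed_motif: str
    evalue: float | None = None
    domain_fail_reason: str | None = None

    def __post_init__(self):
        all_pass = self.evalue_pass and self.length_pass and self.motif_pass and self.domain_pass
        if (self.verdict != "none") != all_pass:
            raise ValueError("verdict must be non-none iff all four filters pass")


# ---------------------------------------------------------------------------
# Viterbi kernel: sequential accumulation, numba-compiled when available.
# ---------------------------------------------------------------------------

def _viterbi_fill_py(msc_x, isc_x, lmm, lmi, lmd, lim, lii, ldm, ldd, VM, VI, VD):
    L, K = msc_x.shape
    NEG = -np.inf
    for i in range(L):
        for j in range(K):
            best = 0.0  # fresh local entry
            if i > 0 and j > 0:
                c = VM[i - 1, j - 1] + lmm[j - 1]
                if c > best:
                    best = c
                c = VI[i - 1, j - 1] + lim[j - 1]
                if c > best:
                    best = c
                c = VD[i - 1, j - 1] + ldm[j - 1]
                if c > best:
                    best = c
            VM[i, j] = msc_x[i, j] + best
        for j in range(K - 1):
            if i > 0:
                a = VM[i - 1, j] + lmi[j]
                b = VI[i - 1, j] + lii[j]
                VI[i, j] = isc_x[i] + (a if a > b else b)
            else:
                VI[i, j] = NEG
        VI[i, K - 1] = NEG
        VD[i, 0] = NEG
        for j in range(1, K):
            a = VM[i, j - 1] + lmd[j - 1]
            b = VD[i, j - 1] + ldd[j - 1]
            VD[i, j] = a if a > b else b
    return VM, VI, VD


try:  # compiled kernel; identical arithmetic to the pure-python fill
    from numba import njit

    _viterbi_fill = njit(cache=False)(_viterbi_fill_py)
except Exception:  # pragma: no cover - numba is an optional accelerator
    _viterbi_fill = _viterbi_fill_py


def _viterbi_matrices(profile: ProfileHMM, codes: np.ndarray):
    msc, isc, logs = profile._score_tables()
    L = codes.shape[0]
    K = profile.n_match
    msc_x = np.ascontiguousarray(msc[:, codes].T)  # (L, K)
    isc_x = np.ascontiguousarray(isc[codes])
    VM = np.empty((L, K))
    VI = np.empty((L, K))
    VD = np.empty((L, K))
    _viterbi_fill(
        msc_x, isc_x,
        logs["mm"], logs["mi"], logs["md"],
        logs["im"], logs["ii"], logs["dm"], logs["dd"],
        VM, VI, VD,
    )
    return msc_x, isc_x, logs, VM, VI, VD


def viterbi_score(profile: ProfileHMM, target: str | np.ndarray) -> float:
    """Best local Viterbi score in bits (no traceback)."""
    codes = target if isinstance(target, np.ndarray) else encode_protein(target)
    if codes.size == 0:
        raise ValueError("empty target sequence")
    *_, VM, _, _ = _viterbi_matrices(profile, codes)
    return float(VM.max())


def viterbi_search(profile: ProfileHMM, target: str, target_id: str = "target") -> HmmHit:
    """Best local alignment of the profile to the target, with traceback.

    The traceback fills the match-column -> residue map (deleted columns map
    to '-'); columns outside the aligned core are absent from the map.
    """
    codes = encode_protein(target)
    if codes.size == 0:
        raise ValueError("empty target sequence")
    msc_x, isc_x, logs, VM, VI, VD = _viterbi_matrices(profile, codes)
    L, K = VM.shape
    flat = int(np.argmax(VM))
    i, j = divmod(flat, K)
    score = float(VM[i, j])
    end_i = i

    lmm, lmi, lmd = logs["mm"], logs["mi"], logs["md"]
    lim, lii = logs["im"], logs["ii"]
    ldm, ldd = logs["dm"], logs["dd"]

    column_map: dict[int, str] = {}
    state = "M"
    start_i = i
    while True:
        if state == "M":
            column_map[j] = target[i]
            start_i = i
            # recompute candidates exactly as the kernel did
            if i > 0 and j > 0:
                cands = [
                    ("M", VM[i - 1, j - 1] + lmm[j - 1]),
                    ("I", VI[i - 1, j - 1] + lim[j - 1]),
                    ("D", VD[i - 1, j - 1] + ldm[j - 1]),
                ]
            else:
                cands = []
            best = 0.0
            best_state = None  # entry
            for s, v in cands:
                if v > best:
                    best, best_state = v, s
            # guard against float drift in base recovery
            if abs((msc_x[i, j] + best) - VM[i, j]) > 1e-9:
                for s, v in cands + [(None, 0.0)]:
                    if msc_x[i, j] + v == VM[i, j]:
                        best_state = s
                        break
            if best_state is None:
                break  # local entry
            state = best_state
            i, j = i - 1, j - 1
        elif state == "I":
            a = VM[i - 1, j] + lmi[j]
            b = VI[i - 1, j] + lii[j]
            state = "M" if a >= b else "I"
            i -= 1
        else:  # D
            a = VM[i, j - 1] + lmd[j - 1]
            b = VD[i, j - 1] + ldd[j - 1]
            column_map[j] = "-"
            state = "M" if a >= b else "D"
            j -= 1
    # deleted columns entered after traceback loop already recorded; ensure
    # the entry column's mapping exists (set in the loop).
    return HmmHit(
        target_id=target_id,
        score=score,
        target_start=start_i + 1,
        target_end=end_i + 1,
        column_map=column_map,
    )


# ---------------------------------------------------------------------------
# Build
# ---------------------------------------------------------------------------

def build_profile(
    msa,
    reference_id: str,
    reference_residue_span: tuple[int, int] | None = None,
    motif_reference_positions: tuple[int, int, int, int] | None = None,
    max_gap_fraction: float = 0.5,
    pseudocount: float = 1.0,
    background: np.ndarray | str = "uniform",
    reference_length: int | None = None,
) -> ProfileHMM:
    """Build a profile from an aligned protein family.

    Columns are restricted to those where the reference sequence has a
    residue inside ``reference_residue_span`` (1-based inclusive residue
    coordinates on the reference; default: the whole reference). Restricted
    columns with more than ``max_gap_fraction`` gaps are demoted to insert
    columns. Emissions use +pseudocount Dirichlet smoothing over the
    20-letter alphabet; transitions are counted from the per-sequence state
    paths with the same smoothing.
    """
    rows = list(msa.items()) if isinstance(msa, dict) else list(msa)
    if not rows:
        raise ProfileBuildError("empty alignment")
    width = len(rows[0][1])
    if any(len(s) != width for _, s in rows):
        raise ProfileBuildError("alignment rows differ in width")
    ref_row = dict(rows).get(reference_id)
    if ref_row is None:
        raise ProfileBuildError(f"reference id {reference_id!r} not in alignment")

    ref_res_at_col = np.full(width, -1, dtype=int)  # 1-based residue index or -1
    r = 0
    for c, ch in enumerate(ref_row):
        if ch != "-":
            r += 1
            ref_res_at_col[c] = r
    ref_total = r
    lo, hi = reference_residue_span or (1, ref_total)
    if not (1 <= lo <= hi <= ref_total):
        raise ProfileBuildError(
            f"span ({lo}, {hi}) outside reference length {ref_total}"
        )

    seqs = [s.upper() for _, s in rows]
    n_rows = len(seqs)
    candidate_cols = [c for c in range(width) if lo <= ref_res_at_col[c] <= hi]
    match_cols = []
    for c in candidate_cols:
        gap_frac = sum(1 for s in seqs if s[c] == "-") / n_rows
        if gap_frac <= max_gap_fraction:
            match_cols.append(c)
    if not match_cols:
        raise ProfileBuildError("no match columns survive the gap filter")
    k = len(match_cols)

    if isinstance(background, str):
        if background == "uniform":
            bg = np.full(20, 1.0 / 20)
        elif background == "alignment":
            counts = np.zeros(20)
            for s in seqs:
                for ch in s:
                    if ch != "-":
                        counts[AA_INDEX[ch]] += 1
            bg = (counts + 1.0) / (counts.sum() + 20.0)
        else:
            raise ValueError(f"unknown background {background!r}")
    else:
        bg = np.asarray(background, dtype=float)

    emis = np.zeros((k, 20))
    for mj, c in enumerate(match_cols):
        for s in seqs:
            ch = s[c]
            if ch != "-":
                if ch not in AA_INDEX:
                    raise ProfileBuildError(f"unknown residue {ch!r} in alignment")
                emis[mj, AA_INDEX[ch]] += 1
        emis[mj] = (emis[mj] + pseudocount) / (emis[mj].sum() + 20 * pseudocount)

    # transition counts from per-row state paths over the match columns
    c_mm = np.zeros(max(k - 1, 1))
    c_mi = np.zeros(max(k - 1, 1))
    c_md = np.zeros(max(k - 1, 1))
    c_im = np.zeros(max(k - 1, 1))
    c_ii = np.zeros(max(k - 1, 1))
    c_dm = np.zeros(max(k - 1, 1))
    c_dd = np.zeros(max(k - 1, 1))
    match_set = set(match_cols)
    for s in seqs:
        for mj in range(k - 1):
            c0, c1 = match_cols[mj], match_cols[mj + 1]
            st0 = "M" if s[c0] != "-" else "D"
            st1 = "M" if s[c1] != "-" else "D"
            n_ins = sum(
                1 for c in range(c0 + 1, c1) if c not in match_set and s[c] != "-"
            )
            if n_ins > 0 and st0 == "M" and st1 == "M":
                c_mi[mj] += 1
                c_ii[mj] += n_ins - 1
                c_im[mj] += 1
            else:
                if st0 == "M":
                    (c_mm if st1 == "M" else c_md)[mj] += 1
                else:
                    (c_dm if st1 == "M" else c_dd)[mj] += 1

    def _norm(parts):
        parts = [p + pseudocount for p in parts]
        total = sum(parts)
        return [p / total for p in parts]

    t_mm = np.empty(max(k - 1, 1))
    t_mi = np.empty_like(t_mm)
    t_md = np.empty_like(t_mm)
    t_im = np.empty_like(t_mm)
    t_ii = np.empty_like(t_mm)
    t_dm = np.empty_like(t_mm)
    t_dd = np.empty_like(t_mm)
    for j in range(max(k - 1, 1)):
        t_mm[j], t_mi[j], t_md[j] = _norm([c_mm[j], c_mi[j], c_md[j]])
        t_im[j], t_ii[j] = _norm([c_im[j], c_ii[j]])
        t_dm[j], t_dd[j] = _norm([c_dm[j], c_dd[j]])

    motif_columns: tuple[int, ...] = ()
    if motif_reference_positions is not None:
        res_to_match = {}
        for mj, c in enumerate(match_cols):
            res_to_match[int(ref_res_at_col[c])] = mj
        cols = []
        for pos in motif_reference_positions:
            if pos not in res_to_match:
                raise ProfileBuildError(
                    f"motif reference position {pos} does not map to a match column"
                )
            cols.append(res_to_match[pos])
        motif_columns = tuple(cols)

    if reference_length is None:
        reference_length = ref_total

    return ProfileHMM(
        match_emissions=emis,
        insert_emissions=bg.copy(),
        background=bg,
        t_mm=t_mm, t_mi=t_mi, t_md=t_md,
        t_im=t_im, t_ii=t_ii,
        t_dm=t_dm, t_dd=t_dd,
        motif_columns=motif_columns,
        reference_length=reference_length,
    )


# ---------------------------------------------------------------------------
# Calibration and E-values
# ---------------------------------------------------------------------------

def fit_gumbel(scores) -> tuple[float, float]:
    """Maximum-likelihood Gumbel fit: returns (mu, lambda) with lambda = 1/scale."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2 or np.var(scores) == 0:
        raise CalibrationError("degenerate (zero-variance) score sample")
    mu, beta = stats.gumbel_r.fit(scores)
    return float(mu), float(1.0 / beta)


def calibrate(
    profile: ProfileHMM,
    n_random: int = 500,
    random_length: int = 350,
    seed: int = 0,
) -> ProfileHMM:
    """Fit a Gumbel null to Viterbi scores of background random sequences.

    Maximum-likelihood location mu and scale beta (lambda = 1/beta) of the
    right-skewed Gumbel; deterministic for a fixed seed.
    """
    if n_random < 200:
        raise ValueError("n_random must be at least 200 for a stable fit")
    rng = np.random.default_rng(seed)
    scores = np.empty(n_random)
    for i in range(n_random):
        codes = rng.choice(20, size=random_length, p=profile.background)
        scores[i] = viterbi_score(profile, codes.astype(np.int64))
    mu, lam = fit_gumbel(scores)
    return dataclasses.replace(profile, mu=mu, lam=lam, calibration_n=n_random)


def score_to_evalue(score: float, profile: ProfileHMM, database_size: int) -> float:
    """Expected number of >= score hits among database_size random targets.

    E = N * (1 - exp(-exp(-lambda (s - mu)))), the Gumbel survival function
    scaled by the search-space size.
    """
    if not profile.is_calibrated:
        raise RuntimeError("profile is not calibrated; run calibrate() first")
    if database_size < 1:
        raise ValueError("database_size must be >= 1")
    x = profile.lam * (score - profile.mu)
    if x < -700:  # survival indistinguishable from 1
        p = 1.0
    else:
        p = float(-np.expm1(-np.exp(-x)))
    return database_size * p


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_bilr(
    hit: HmmHit,
    target_sequence: str,
    domain_annotations,
    profile: ProfileHMM,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    min_length_fraction: float = DEFAULT_MIN_LENGTH_FRACTION,
    motif: str = DEFAULT_MOTIF,
    motif_mode: str = "columns",
) -> BilRCall:
    """Apply the four-part BilR filter to one hit.

    motif_mode "columns" (default) reads the residues aligned to the four
    motif match columns; "regex" falls back to a substring search over the
    raw sequence.
    """
    if not profile.motif_columns and motif_mode == "columns":
        raise ValueError("profile carries no motif columns")
    if not profile.reference_length:
        raise ValueError("profile carries no reference length")

    evalue_pass = hit.evalue is not None and hit.evalue < evalue_max
    length_pass = len(target_sequence) >= min_length_fraction * profile.reference_length

    if motif_mode == "columns":
        observed = "".join(
            hit.column_map.get(c, "-") for c in profile.motif_columns
        )
        motif_pass = observed == motif
    elif motif_mode == "regex":
        observed = motif if motif in target_sequence else ""
        motif_pass = bool(observed)
    else:
        raise ValueError(f"unknown motif_mode {motif_mode!r}")

    domain_fail_reason = None
    if domain_annotations is None:
        domain_pass = False
        domain_set = set()
        domain_fail_reason = "unannotated"
    else:
        domain_set = set(domain_annotations)
        domain_pass = domain_set in ({PF_TIM_BARREL}, {PF_FLAVODOXIN, PF_TIM_BARREL})
        if not domain_pass:
            domain_fail_reason = "unexpected domain architecture"

    if evalue_pass and length_pass and motif_pass and domain_pass:
        verdict = "long" if domain_set == {PF_FLAVODOXIN, PF_TIM_BARREL} else "short"
    else:
        verdict = "none"
    return BilRCall(
        target_id=hit.target_id,
        verdict=verdict,
        evalue_pass=evalue_pass,
        length_pass=length_pass,
        motif_pass=motif_pass,
        domain_pass=domain_pass,
        observed_motif=observed,
        evalue=hit.evalue,
        domain_fail_reason=domain_fail_reason,
    )


def search(
    profile: ProfileHMM,
    targets,
    database_size: int | None = None,
) -> list[HmmHit]:
    """Viterbi-search every target; attach calibrated E-values.

    ``targets`` is a list of (id, sequence) or a dict id -> sequence. Hits
    are computed independently per target, so database order cannot change
    any per-target result (only the shared database_size enters E-values).
    """
    items = sorted(targets.items()) if isinstance(targets, dict) else list(targets)
    n = database_size if database_size is not None else len(items)
    hits = []
    for tid, seq in items:
        hit = viterbi_search(profile, seq, target_id=tid)
        hit.evalue = score_to_evalue(hit.score, profile, n)
        hits.append(hit)
    return hits


def scan_database(
    profile: ProfileHMM,
    targets,
    domain_table: dict[str, list[str]] | None = None,
    database_size: int | None = None,
    **thresholds,
) -> list[BilRCall]:
    """Full scan: search every target and classify each hit."""
    items = sorted(targets.items()) if isinstance(targets, dict) else list(targets)
    seqs = dict(items)
    hits = search(profile, items, database_size=database_size)
    calls = []
    for hit in hits:
        domains = None
        if domain_table is not None:
            domains = domain_table.get(hit.target_id)
        calls.append(
            classify_bilr(hit, seqs[hit.target_id], domains, profile, **thresholds)
        )
    return calls
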