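"""Metagenomic bilR presence profiling and cohort prevalence comparison.

Per sample: remove host-contaminant reads (k-mer sharing against the host
reference), drop samples below the read-count floor, count reads mapping to
the bilR gene reference set (exact k-mer seed + ungapped extension, both
strands, each read counted at most once), convert to counts per million
(CPM), and call bilR present when CPM is strictly greater than 5. Cohort
prevalence differences use the two-sample test of equal proportions with
R's prop.test semantics (Yates continuity correction, capped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .reads import ReadSet, encode, kmer_valid, kmer_values, revcomp_codes

__all__ = [
    "SampleProfile",
    "PrevalenceResult",
    "subtract_host",
    "qc_sample",
    "map_reads",
    "compute_cpm",
    "call_presence",
    "profile_sample",
    "bin_by_age",
    "prevalence_test",
    "cohort_filter",
]

DEFAULT_CPM_THRESHOLD = 5.0
DEFAULT_MIN_READS = 1_000_000
DEFAULT_HOST_K = 31
DEFAULT_MAP_K = 21
DEFAULT_MIN_IDENTITY = 0.9

COHORTS = ("infant", "healthy_adult", "ibd_cd", "ibd_uc", "other")
HEALTHY_ADULT_MIN_AGE_DAYS = 3 * 365  # exclude healthy samples below 3 years


@dataclass
class SampleProfile:
    """Per-metagenome read accounting and the presence call."""

    sample_id: str
    total_reads: int  # after host removal
    mapped_reads: int
    cpm: float
    present: bool
    qc_pass: bool
    cohort: str = "other"
    age_days: int | None = None

    def __post_init__(self):
        if self.total_reads > 0 and self.qc_pass:
            expected = self.mapped_reads / self.total_reads * 1e6
            if abs(self.cpm - expected) > 1e-6:
                raise ValueError("cpm inconsistent with mapped/total")


@dataclass
class PrevalenceResult:
    """Two-group equal-proportion comparison (proportions of bilR-absent)."""

    group_labels: tuple[str, str]
    n: tuple[int, int]
    n_absent: tuple[int, int]
    proportion_difference: float
    statistic: float
    p_value: float
    continuity_correction: bool


def _as_readset(reads) -> ReadSet:
    return reads if isinstance(reads, ReadSet) else ReadSet.from_triples(reads)


# ---------------------------------------------------------------------------
# Inner k-mer loops (numba-compiled when available; numpy fallback below)
# ---------------------------------------------------------------------------

def _host_decision_py(codes, host_sorted, k, min_frac):
    vals = kmer_values(codes, k)
    valid = (
        kmer_valid(codes, k)
        if (codes >= 4).any()
        else np.ones(vals.shape, dtype=bool)
    )
    shared = _membership(vals, host_sorted) & valid
    n_windows = codes.shape[1] - k + 1
    return shared.sum(axis=1) / n_windows >= min_frac


def _map_decision_py(codes, ref_rows, ref_lens, kmer_sorted, offsets, entry_row, entry_pos, k, min_identity):
    n, L = codes.shape
    need = int(np.ceil(min_identity * L))
    vals = kmer_values(codes, k)
    valid = (
        kmer_valid(codes, k)
        if (codes >= 4).any()
        else np.ones(vals.shape, dtype=bool)
    )
    hits = _membership(vals, kmer_sorted) & valid
    mapped = np.zeros(n, dtype=np.bool_)
    for i in np.flatnonzero(hits.any(axis=1)):
        for p in np.flatnonzero(hits[i]):
            idx = int(np.searchsorted(kmer_sorted, vals[i, p]))
            for e in range(offsets[idx], offsets[idx + 1]):
                r, rp = int(entry_row[e]), int(entry_pos[e])
                off = rp - int(p)
                lo, hi = max(0, -off), min(L, int(ref_lens[r]) - off)
                if hi <= lo:
                    continue
                m = int((codes[i, lo:hi] == ref_rows[r, off + lo : off + hi]).sum())
                if m >= need:
                    mapped[i] = True
                    break
            if mapped[i]:
                break
    return mapped


_host_decision = _host_decision_py
_map_decision = _map_decision_py

try:
    from numba import njit

    @njit(cache=False)
    def _host_decision_nb(codes, host_sorted, k, min_frac):  # pragma: no cover
        n, L = codes.shape
        n_windows = L - k + 1
        need = int(np.ceil(min_frac * n_windows))
        if need < 1:
            need = 1
        mask = (np.uint64(1) << np.uint64(2 * k)) - np.uint64(1)
        out = np.zeros(n, dtype=np.bool_)
        m = host_sorted.size
        for i in range(n):
            v = np.uint64(0)
            since_bad = 0
            shared = 0
            for q in range(L):
                c = codes[i, q]
                if c >= 4:
                    since_bad = 0
                    v = (v << np.uint64(2)) & mask
                else:
                    since_bad += 1
                    v = ((v << np.uint64(2)) | np.uint64(c)) & mask
                if q >= k - 1 and since_bad >= k:
                    lo, hi = 0, m
                    while lo < hi:
                        mid = (lo + hi) // 2
                        if host_sorted[mid] < v:
                            lo = mid + 1
                        else:
                            hi = mid
                    if lo < m and host_sorted[lo] == v:
                        shared += 1
                        if shared >= need:
                            out[i] = True
                            break
                windows_left = L - 1 - q
                if shared + windows_left < need:
                    break
        return out

    @njit(cache=False)
    def _map_decision_nb(codes, ref_rows, ref_lens, kmer_sorted, offsets, entry_row, entry_pos, k, min_identity):  # pragma: no cover
        n, L = codes.shape
        need = int(np.ceil(min_identity * L))
        mask = (np.uint64(1) << np.uint64(2 * k)) - np.uint64(1)
        out = np.zeros(n, dtype=np.bool_)
        m = kmer_sorted.size
        for i in range(n):
            v = np.uint64(0)
            since_bad = 0
            for q in range(L):
                c = codes[i, q]
                if c >= 4:
                    since_bad = 0
                    v = (v << np.uint64(2)) & mask
                else:
                    since_bad += 1
                    v = ((v << np.uint64(2)) | np.uint64(c)) & mask
                if q < k - 1 or since_bad < k:
                    continue
                lo, hi = 0, m
                while lo < hi:
                    mid = (lo + hi) // 2
                    if kmer_sorted[mid] < v:
                        lo = mid + 1
                    else:
                        hi = mid
                if lo >= m or kmer_sorted[lo] != v:
                    continue
                p = q - k + 1
                for e in range(offsets[lo], offsets[lo + 1]):
                    r = entry_row[e]
                    off = entry_pos[e] - p
                    matches = 0
                    for t in range(L):
                        rt = off + t
                        if 0 <= rt < ref_lens[r] and ref_rows[r, rt] == codes[i, t]:
                            matches += 1
                    if matches >= need:
                        out[i] = True
                        break
                if out[i]:
                    break
        return out

    _host_decision = _host_decision_nb
    _map_decision = _map_decision_nb
except Exception:  # pragma: no cover - numba is an optional accelerator
    pass


def _reference_kmers(ref_codes_list, k: int) -> np.ndarray:
    """Sorted unique k-mer values of the references, both strands."""
    chunks = []
    for codes in ref_codes_list:
        for strand in (codes, revcomp_codes(codes)):
            vals = kmer_values(strand[None, :], k)[0]
            ok = kmer_valid(strand[None, :], k)[0]
            chunks.append(vals[ok])
    if not chunks:
        return np.empty(0, dtype=np.uint64)
    return np.unique(np.concatenate(chunks))


def _membership(vals: np.ndarray, sorted_set: np.ndarray) -> np.ndarray:
    if sorted_set.size == 0:
        return np.zeros(vals.shape, dtype=bool)
    idx = np.searchsorted(sorted_set, vals)
    idx[idx == sorted_set.size] = 0
    return sorted_set[idx] == vals


def subtract_host(
    reads,
    host_reference: str,
    k: int = DEFAULT_HOST_K,
    min_shared_fraction: float = 0.5,
) -> ReadSet:
    """Remove reads sharing >= min_shared_fraction of k-mers with the host.

    The shared fraction is over all L-k+1 windows of the read (windows with
    ambiguous bases count as unshared). Host k-mers are strand-collapsed
    (forward and reverse complement both indexed). Order of the retained
    reads is preserved.
    """
    if not host_reference:
        raise ValueError("empty host reference")
    rs = _as_readset(reads)
    if len(rs) == 0:
        return rs
    if k > rs.read_length:
        raise ValueError(f"k={k} exceeds read length {rs.read_length}")
    host = _reference_kmers([encode(host_reference)], k)
    is_host = _host_decision(rs.codes, host, k, min_shared_fraction)
    return rs.subset(~np.asarray(is_host))


def qc_sample(reads, min_reads: int = DEFAULT_MIN_READS) -> bool:
    """True iff the sample keeps at least min_reads reads (inclusive)."""
    n = len(reads) if hasattr(reads, "__len__") else sum(1 for _ in reads)
    return n >= min_reads


def map_reads(
    reads,
    gene_references: list[str],
    k: int = DEFAULT_MAP_K,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    return_mask: bool = False,
):
    """Count reads mapping to any bilR reference gene.

    A read maps iff it shares an exact k-mer seed with a reference (either
    strand) and the ungapped extension along the seed diagonal reaches
    min_identity over the full read (positions hanging off the reference
    count as mismatches). Each read is counted at most once.
    """
    if not gene_references:
        raise ValueError("empty gene reference set")
    rs = _as_readset(reads)
    if len(rs) == 0:
        return (0, np.zeros(0, dtype=bool)) if return_mask else 0
    if k > rs.read_length:
        raise ValueError(f"k={k} exceeds read length {rs.read_length}")

    # index both strands of every reference; reads are then queried forward
    variant_codes = []
    for r in gene_references:
        codes = encode(r)
        variant_codes.append(codes)
        variant_codes.append(revcomp_codes(codes))
    max_len = max(c.size for c in variant_codes)
    ref_rows = np.full((len(variant_codes), max_len), 4, dtype=np.uint8)
    ref_lens = np.empty(len(variant_codes), dtype=np.int64)
    for r, codes in enumerate(variant_codes):
        ref_rows[r, : codes.size] = codes
        ref_lens[r] = codes.size

    all_vals, all_rows, all_pos = [], [], []
    for r, codes in enumerate(variant_codes):
        vals = kmer_values(codes[None, :], k)[0]
        ok = kmer_valid(codes[None, :], k)[0]
        pos = np.flatnonzero(ok)
        all_vals.append(vals[pos])
        all_rows.append(np.full(pos.size, r, dtype=np.int64))
        all_pos.append(pos.astype(np.int64))
    vals = np.concatenate(all_vals)
    order = np.argsort(vals, kind="stable")
    vals = vals[order]
    entry_row = np.concatenate(all_rows)[order]
    entry_pos = np.concatenate(all_pos)[order]
    kmer_sorted, starts = np.unique(vals, return_index=True)
    offsets = np.append(starts, vals.size).astype(np.int64)

    mapped = np.asarray(
        _map_decision(
            rs.codes, ref_rows, ref_lens, kmer_sorted, offsets,
            entry_row, entry_pos, k, min_identity,
        )
    )
    count = int(mapped.sum())
    return (count, mapped) if return_mask else count


def compute_cpm(mapped: int, total: int) -> float:
    """bilR counts per million: mapped / total * 1e6."""
    if total <= 0:
        raise ValueError("total read count must be positive")
    if mapped < 0 or mapped > total:
        raise ValueError("mapped count must lie in [0, total]")
    return mapped / total * 1e6


def call_presence(cpm: float, threshold: float = DEFAULT_CPM_THRESHOLD) -> bool:
    """bilR present iff CPM strictly greater than the threshold (default 5)."""
    if cpm < 0:
        raise ValueError("CPM cannot be negative")
    return cpm > threshold


def profile_sample(
    sample_id: str,
    reads,
    gene_references: list[str],
    host_reference: str,
    cohort: str = "other",
    age_days: int | None = None,
    min_reads: int = DEFAULT_MIN_READS,
    cpm_threshold: float = DEFAULT_CPM_THRESHOLD,
    host_k: int = DEFAULT_HOST_K,
    map_k: int = DEFAULT_MAP_K,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_shared_fraction: float = 0.5,
    cpm_denominator: str = "post_host",
) -> SampleProfile:
    """Run the per-sample workflow: host removal -> QC -> mapping -> CPM.

    ``cpm_denominator`` chooses the CPM total: reads surviving host removal
    (default, the count available at the alignment step) or the raw input
    count ("raw").
    """
    rs = _as_readset(reads)
    raw_total = len(rs)
    kept = subtract_host(rs, host_reference, k=host_k, min_shared_fraction=min_shared_fraction)
    qc = qc_sample(kept, min_reads=min_reads)
    total = raw_total if cpm_denominator == "raw" else len(kept)
    if not qc or total == 0:
        return SampleProfile(
            sample_id=sample_id, total_reads=len(kept), mapped_reads=0,
            cpm=0.0, present=False, qc_pass=False, cohort=cohort, age_days=age_days,
        )
    mapped = map_reads(kept, gene_references, k=map_k, min_identity=min_identity)
    cpm = compute_cpm(mapped, total)
    return SampleProfile(
        sample_id=sample_id,
        total_reads=total,
        mapped_reads=mapped,
        cpm=cpm,
        present=call_presence(cpm, cpm_threshold),
        qc_pass=True,
        cohort=cohort,
        age_days=age_days,
    )


def bin_by_age(
    samples: list[SampleProfile],
    bin_width_days: int = 30,
    range_days: int = 365,
) -> dict[int, tuple[int, int, float]]:
    """Bin QC-passing samples by age; report per-bin bilR absence.

    Bins are half-open [30i, 30(i+1)); samples with no age, or age beyond
    range_days, are excluded. Returns bin -> (n, n_absent, percent_absent).
    """
    counts: dict[int, list[int]] = {}
    for s in samples:
        if not s.qc_pass or s.age_days is None:
            continue
        if s.age_days < 0:
            raise ValueError(f"negative age for sample {s.sample_id}")
        if s.age_days > range_days:
            continue
        b = s.age_days // bin_width_days
        n, absent = counts.setdefault(b, [0, 0])
        counts[b][0] = n + 1
        counts[b][1] = absent + (0 if s.present else 1)
    return {
        b: (n, absent, absent / n * 100.0)
        for b, (n, absent) in sorted(counts.items())
    }


def prevalence_test(
    absent_1: int,
    n_1: int,
    absent_2: int,
    n_2: int,
    continuity_correction: bool = True,
    labels: tuple[str, str] = ("group1", "group2"),
) -> PrevalenceResult:
    """Two-sample test of equal proportions, matching R's prop.test.

    The chi-square statistic on the 2x2 table, with the Yates continuity
    correction capped at |p1 - p2| / (1/n1 + 1/n2) so equal proportions give
    statistic 0 and p = 1; p-value from chi-square with 1 df (two-sided).
    """
    for a, n in ((absent_1, n_1), (absent_2, n_2)):
        if n < 1:
            raise ValueError("group sizes must be >= 1")
        if not 0 <= a <= n:
            raise ValueError("counts must satisfy 0 <= absent <= n")
    x = np.array([[absent_1, n_1 - absent_1], [absent_2, n_2 - absent_2]], dtype=float)
    expected = np.outer(x.sum(axis=1), x.sum(axis=0)) / x.sum()
    if np.any(expected == 0):
        raise ValueError("degenerate contingency table (zero expected count)")
    p1, p2 = absent_1 / n_1, absent_2 / n_2
    yates = 0.0
    if continuity_correction:
        yates = min(0.5, abs(p1 - p2) / (1.0 / n_1 + 1.0 / n_2))
    statistic = float(np.sum((np.abs(x - expected) - yates) ** 2 / expected))
    p_value = float(stats.chi2.sf(statistic, df=1))
    return PrevalenceResult(
        group_labels=labels,
        n=(n_1, n_2),
        n_absent=(absent_1, absent_2),
        proportion_difference=p1 - p2,
        statistic=statistic,
        p_value=p_value,
        continuity_correction=continuity_correction,
    )


def cohort_filter(
    samples: list[SampleProfile],
    healthy_min_age_days: int = HEALTHY_ADULT_MIN_AGE_DAYS,
) -> tuple[dict[str, list[SampleProfile]], dict[str, int]]:
    """Apply per-cohort inclusion rules; return retained groups + audit.

    healthy_adult samples with a recorded age below 3 years are excluded;
    IBD samples are split into CD and UC groups; infants are retained for
    age binning. Unknown cohort labels raise.
    """
    groups: dict[str, list[SampleProfile]] = {
        "infant": [], "healthy_adult": [], "CD": [], "UC": [], "other": []
    }
    audit = {"excluded_healthy_young": 0, "excluded_qc": 0}
    for s in samples:
        if s.cohort not in COHORTS:
            raise ValueError(f"unknown cohort label {s.cohort!r}")
        if not s.qc_pass:
            audit["excluded_qc"] += 1
            continue
        if s.cohort == "healthy_adult":
            if s.age_days is not None and s.age_days < healthy_min_age_days:
                audit["excluded_healthy_young"] += 1
                continue
            groups["healthy_adult"].append(s)
        elif s.cohort == "ibd_cd":
            groups["CD"].append(s)
        elif s.cohort == "ibd_uc":
            groups["UC"].append(s)
        else:
            groups[s.cohort].append(s)
    return groups, audit
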