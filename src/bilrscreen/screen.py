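"""Phenotype-guided comparative screen for candidate reductase genes.

Proteins from reducer and non-reducer strains are clustered into orthogroups
by reciprocal-best-hit (RBH) Smith-Waterman alignment, groups are filtered to
putative oxidoreductases (at least three members carrying an EC class-1
label), and the survivors are matched against the reducer/non-reducer
phenotype: a candidate must be present in every reducer strain and absent
from every non-reducer strain.

The RBH clustering is a transparent stand-in with the same output contract
as a dedicated orthology tool: a partition of the protein universe into
groups with per-strain presence vectors.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "Orthogroup",
    "ScreenResult",
    "align_score",
    "self_score",
    "cluster_orthogroups",
    "filter_oxidoreductase",
    "phenotype_pattern_screen",
    "screen_candidates",
]

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
_EC_RE = re.compile(r"^\d+(\.(\d+|-)){0,3}$")

REDUCER = "reducer"
NON_REDUCER = "non_reducer"


def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner(mode="local")
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # a gap of length L costs gap_open + L * gap_extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _check_protein(seq: str) -> None:
    bad = set(seq) - AA_ALPHABET
    if not seq:
        raise ValueError("empty protein sequence")
    if bad:
        raise ValueError(f"unknown residue(s) {sorted(bad)} in protein sequence")


def align_score(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> float:
    """Smith-Waterman local alignment score with affine gaps (symmetric)."""
    _check_protein(a)
    _check_protein(b)
    return float(_make_aligner(matrix, gap_open, gap_extend).score(a, b))


def self_score(seq: str, matrix: str = "BLOSUM62") -> float:
    """Sum of diagonal substitution scores over the sequence."""
    _check_protein(seq)
    m = substitution_matrices.load(matrix)
    return float(sum(m[c, c] for c in seq))


@dataclass
class Orthogroup:
    """A cluster of proteins across strains with its strain-presence vector."""

    group_id: str
    members: list[tuple[str, str]]  # (protein_id, strain_id)

    @property
    def protein_ids(self) -> list[str]:
        return [p for p, _ in self.members]

    @property
    def strains(self) -> set[str]:
        return {s for _, s in self.members}

    def presence_vector(self, strains) -> dict[str, bool]:
        here = self.strains
        return {s: s in here for s in strains}

    def ec_member_count(self, ec_table: dict[str, str], ec_class: str = "1") -> int:
        n = 0
        for pid, _ in self.members:
            ec = ec_table.get(pid)
            if ec is None:
                continue
            if not _EC_RE.match(ec):
                warnings.warn(f"malformed EC string {ec!r} for {pid}; treating as unannotated")
                continue
            if ec.split(".")[0] == ec_class:
                n += 1
        return n


@dataclass
class ScreenResult:
    """Candidate orthogroups with a per-group audit of both filters."""

    candidates: list[str]
    audit: dict[str, dict]
    phenotype: dict[str, str] = field(default_factory=dict)


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def cluster_orthogroups(
    proteomes: dict[str, list[tuple[str, str]]],
    min_score_ratio: float = 0.3,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    prefilter_k: int | None = 5,
) -> list[Orthogroup]:
    """Partition proteins into orthogroups via reciprocal best hits.

    A hit of protein x into strain T is the best-scoring protein of T with
    score >= min_score_ratio * self_score(x) (ties broken by lexicographic
    protein id). RBH pairs form edges; connected components are the groups;
    proteins without any reciprocal hit become singletons.

    ``prefilter_k`` skips alignment of pairs sharing no length-k peptide word
    (exact-word pre-screen; set to None to align every cross-strain pair).
    """
    if len(proteomes) < 2:
        raise ValueError("need at least two strains to cluster orthogroups")
    for strain, prots in proteomes.items():
        if not prots:
            raise ValueError(f"empty proteome for strain {strain!r}")

    aligner = _make_aligner(matrix, gap_open, gap_extend)
    strain_of: dict[str, str] = {}
    seq_of: dict[str, str] = {}
    for strain, prots in proteomes.items():
        for pid, seq in prots:
            if pid in strain_of:
                raise ValueError(f"duplicate protein id {pid!r}")
            _check_protein(seq)
            strain_of[pid] = strain
            seq_of[pid] = seq
    selfs = {pid: self_score(seq, matrix) for pid, seq in seq_of.items()}
    words = (
        {pid: _kmer_set(seq, prefilter_k) for pid, seq in seq_of.items()}
        if prefilter_k
        else None
    )

    score_cache: dict[tuple[str, str], float] = {}

    def score(x: str, y: str) -> float:
        key = (x, y) if x <= y else (y, x)
        if key not in score_cache:
            if words is not None and not (words[x] & words[y]):
                score_cache[key] = 0.0
            else:
                score_cache[key] = float(aligner.score(seq_of[x], seq_of[y]))
        return score_cache[key]

    strains = sorted(proteomes)
    ids_by_strain = {s: sorted(pid for pid, _ in proteomes[s]) for s in strains}

    def best_hit(x: str, target: str) -> str | None:
        cutoff = min_score_ratio * selfs[x]
        best_id, best_sc = None, None
        for y in ids_by_strain[target]:  # lexicographic order breaks ties
            sc = score(x, y)
            if sc >= cutoff and (best_sc is None or sc > best_sc):
                best_id, best_sc = y, sc
        return best_id

    parent = {pid: pid for pid in strain_of}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for i, s in enumerate(strains):
        for t in strains[i + 1 :]:
            for x in ids_by_strain[s]:
                y = best_hit(x, t)
                if y is not None and best_hit(y, s) == x:
                    union(x, y)

    components: dict[str, list[str]] = {}
    for pid in sorted(strain_of):
        components.setdefault(find(pid), []).append(pid)
    groups = []
    for gi, root in enumerate(sorted(components)):
        members = [(pid, strain_of[pid]) for pid in components[root]]
        groups.append(Orthogroup(group_id=f"OG{gi:05d}", members=members))
    return groups


def filter_oxidoreductase(
    groups: list[Orthogroup],
    ec_table: dict[str, str],
    min_members: int = 3,
    all_members: bool = False,
) -> list[Orthogroup]:
    """Keep groups with >= min_members proteins carrying an EC class-1 label.

    ``all_members=True`` switches to the stricter reading: every member is
    class-1 annotated and the group has more than two members.
    """
    kept = []
    for g in groups:
        n_ox = g.ec_member_count(ec_table)
        if all_members:
            ok = len(g.members) >= min_members and n_ox == len(g.members)
        else:
            ok = n_ox >= min_members
        if ok:
            kept.append(g)
    return kept


def _validate_phenotype(phenotype: dict[str, str]) -> tuple[set[str], set[str]]:
    bad = {v for v in phenotype.values() if v not in (REDUCER, NON_REDUCER)}
    if bad:
        raise ValueError(f"unknown phenotype label(s): {sorted(bad)}")
    reducers = {s for s, v in phenotype.items() if v == REDUCER}
    non_reducers = {s for s, v in phenotype.items() if v == NON_REDUCER}
    if not reducers or not non_reducers:
        raise ValueError("need at least one reducer and one non-reducer strain")
    return reducers, non_reducers


def phenotype_pattern_screen(
    groups: list[Orthogroup],
    phenotype: dict[str, str],
    mode: str = "strict",
) -> ScreenResult:
    """Match orthogroup presence/absence patterns to the reducer phenotype.

    strict: keep groups present in every reducer, absent from every
    non-reducer. scored: rank all groups by Hamming distance between the
    presence vector and the phenotype vector (distance 0 == strict match).
    """
    if mode not in ("strict", "scored"):
        raise ValueError(f"unknown mode {mode!r}")
    reducers, non_reducers = _validate_phenotype(phenotype)
    strains = set(phenotype)
    audit: dict[str, dict] = {}
    scored: list[tuple[int, str]] = []
    for g in groups:
        missing = g.strains - strains
        if missing:
            raise ValueError(
                f"phenotype missing for strain(s) {sorted(missing)} in group {g.group_id}"
            )
        here = g.strains
        dist = sum(1 for s in reducers if s not in here) + sum(
            1 for s in non_reducers if s in here
        )
        audit[g.group_id] = {"hamming_distance": dist, "phenotype_match": dist == 0}
        scored.append((dist, g.group_id))
    if mode == "strict":
        candidates = sorted(gid for d, gid in scored if d == 0)
    else:
        candidates = [gid for _, gid in sorted(scored)]
    return ScreenResult(candidates=candidates, audit=audit, phenotype=dict(phenotype))


def screen_candidates(
    groups: list[Orthogroup],
    ec_table: dict[str, str],
    phenotype: dict[str, str],
    min_members: int = 3,
    all_members: bool = False,
    mode: str = "strict",
) -> ScreenResult:
    """Full screen: oxidoreductase filter composed with the phenotype pattern.

    The two filters act on disjoint criteria and commute; candidates are the
    groups passing both, with a per-group audit of each.
    """
    ox = {g.group_id for g in filter_oxidoreductase(groups, ec_table, min_members, all_members)}
    pheno = phenotype_pattern_screen(groups, phenotype, mode="strict")
    audit = {}
    for g in groups:
        audit[g.group_id] = {
            "oxidoreductase_pass": g.group_id in ox,
            **pheno.audit[g.group_id],
        }
    if mode == "strict":
        candidates = sorted(gid for gid in pheno.candidates if gid in ox)
    else:
        order = sorted(audit, key=lambda gid: (audit[gid]["hamming_distance"], gid))
        candidates = [gid for gid in order if gid in ox]
    return ScreenResult(candidates=candidates, audit=audit, phenotype=dict(phenotype))
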