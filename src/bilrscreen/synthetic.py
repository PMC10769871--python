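"""Synthetic fixtures with recorded ground truth for every pipeline stage.

Four generators emulate the study's real inputs at desk scale:

* :func:`generate_pangenome` — reducer/non-reducer strain proteomes with one
  planted causal orthogroup whose presence exactly tracks phenotype, a
  background accessory genome (i.i.d. Bernoulli presence), and an EC table;
* :func:`generate_bilr_family` — a BilR-like protein family: short
  (TIM-barrel only) and long (flavodoxin + TIM-barrel) clade-1 members
  sharing a conserved HGDR motif, plus decoys that each violate exactly one
  classification filter;
* :func:`generate_metagenome` — shotgun read sets with known per-sample
  bilR read counts, host contamination and substitution error;
* :func:`generate_fluorescence` — assay replicate tables with a known
  reducer effect size.

Every generator is byte-reproducible for a fixed seed and asserts its own
truth invariants on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hmm import AA, DEFAULT_MOTIF, PF_FLAVODOXIN, PF_TIM_BARREL
from .reads import ReadSet, encode, revcomp_codes
from .screen import NON_REDUCER, REDUCER, Orthogroup

__all__ = [
    "PangenomeFixture",
    "BilrFamilyFixture",
    "MetagenomeFixture",
    "FluorescenceFixture",
    "generate_pangenome",
    "generate_bilr_family",
    "generate_metagenome",
    "generate_fluorescence",
]

_AA_ARR = np.frombuffer(AA.encode(), dtype=np.uint8)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return _AA_ARR[rng.integers(0, 20, size=length)].tobytes().decode()


def _mutate_protein(
    rng: np.random.Generator, seq: str, rate: float, frozen: set[int] = frozenset()
) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hit:
        if int(i) in frozen:
            continue
        choices = _AA_ARR[_AA_ARR != arr[i]]
        arr[i] = choices[rng.integers(0, choices.size)]
    return arr.tobytes().decode()


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return np.frombuffer(b"ACGT", dtype=np.uint8)[
        rng.integers(0, 4, size=length)
    ].tobytes().decode()


# ---------------------------------------------------------------------------
# Pangenome
# ---------------------------------------------------------------------------

@dataclass
class PangenomeFixture:
    """Strain proteomes + phenotype + EC table with a planted causal group."""

    proteomes: dict[str, list[tuple[str, str]]]
    phenotype: dict[str, str]
    ec_table: dict[str, str]
    truth_causal_group: set[str]
    group_members: dict[str, list[str]]
    causal_group_id: str | None
    seed: int
    presence_p: float

    def __post_init__(self):
        ids = [pid for prots in self.proteomes.values() for pid, _ in prots]
        if len(ids) != len(set(ids)):
            raise AssertionError("protein ids must be unique")
        for strain, prots in self.proteomes.items():
            if not prots:
                raise AssertionError(f"strain {strain} has no proteins")
        strain_of = {
            pid: s for s, prots in self.proteomes.items() for pid, _ in prots
        }
        causal_strains = {strain_of[p] for p in self.truth_causal_group}
        reducers = {s for s, v in self.phenotype.items() if v == REDUCER}
        non_reducers = set(self.phenotype) - reducers
        if self.truth_causal_group:
            if causal_strains != reducers or causal_strains & non_reducers:
                raise AssertionError("causal group must exactly track phenotype")

    def orthogroups(self) -> list[Orthogroup]:
        """Recorded group membership as Orthogroup objects (clustering truth)."""
        strain_of = {
            pid: s for s, prots in self.proteomes.items() for pid, _ in prots
        }
        return [
            Orthogroup(group_id=gid, members=[(p, strain_of[p]) for p in pids])
            for gid, pids in sorted(self.group_members.items())
        ]


def generate_pangenome(
    n_reducers: int,
    n_nonreducers: int,
    n_groups: int,
    causal: bool,
    noise: float,
    seed: int,
    presence_p: float = 0.7,
    oxidoreductase_rate: float = 0.06,
    other_ec_rate: float = 0.4,
) -> PangenomeFixture:
    """Pangenome with i.i.d. Bernoulli(presence_p) background orthogroups.

    When ``causal`` is true, one group (the last index) is planted so its
    presence exactly matches the reducer phenotype, and its members carry an
    EC class-1 label. A fraction ``oxidoreductase_rate`` of background
    groups (matching the oxidoreductase share seen in real annotation
    screens) is class-1 themed; ``other_ec_rate`` gets a non-1 EC; the rest
    stay unannotated. Substitutions at rate ``noise`` per residue; the
    causal core is indel-free so motif positions stay addressable.
    """
    if n_reducers < 1 or n_nonreducers < 1:
        raise ValueError("need at least one reducer and one non-reducer strain")
    if n_groups < 2:
        raise ValueError("need at least two orthogroups")
    if not 0 <= noise < 0.3:
        raise ValueError("noise must lie in [0, 0.3)")
    rng = np.random.default_rng(seed)
    reducers = [f"R{i + 1:02d}" for i in range(n_reducers)]
    non_reducers = [f"N{i + 1:02d}" for i in range(n_nonreducers)]
    strains = reducers + non_reducers
    phenotype = {s: REDUCER for s in reducers} | {s: NON_REDUCER for s in non_reducers}

    proteomes: dict[str, list[tuple[str, str]]] = {s: [] for s in strains}
    ec_table: dict[str, str] = {}
    group_members: dict[str, list[str]] = {}
    n_background = n_groups - (1 if causal else 0)

    for gi in range(n_background):
        gid = f"G{gi:04d}"
        length = int(rng.integers(80, 161))
        ancestor = _random_protein(rng, length)
        u = rng.random()
        if u < oxidoreductase_rate:
            ec = f"1.{rng.integers(1, 21)}.{rng.integers(1, 21)}.{rng.integers(1, 99)}"
        elif u < oxidoreductase_rate + other_ec_rate:
            ec = f"{rng.integers(2, 7)}.{rng.integers(1, 21)}.{rng.integers(1, 21)}.{rng.integers(1, 99)}"
        else:
            ec = None
        present = rng.random(len(strains)) < presence_p
        members = []
        for s, here in zip(strains, present):
            if not here:
                continue
            pid = f"{s}_{gid}"
            seq = _mutate_protein(rng, ancestor, noise)
            # occasional short indel: background groups only
            if rng.random() < 0.15 and len(seq) > 20:
                pos = int(rng.integers(5, len(seq) - 6))
                if rng.random() < 0.5:
                    seq = seq[:pos] + seq[pos + int(rng.integers(1, 6)) :]
                else:
                    seq = seq[:pos] + _random_protein(rng, int(rng.integers(1, 6))) + seq[pos:]
            proteomes[s].append((pid, seq))
            members.append(pid)
            if ec is not None:
                ec_table[pid] = ec
        if members:
            group_members[gid] = members

    truth_causal: set[str] = set()
    causal_group_id = None
    if causal:
        causal_group_id = f"G{n_background:04d}"
        ancestor = _random_protein(rng, 350)
        members = []
        for s in reducers:
            pid = f"{s}_{causal_group_id}"
            proteomes[s].append((pid, _mutate_protein(rng, ancestor, noise)))
            ec_table[pid] = "1.6.99.1"
            members.append(pid)
            truth_causal.add(pid)
        group_members[causal_group_id] = members

    # invariant: every strain carries at least one protein
    for s in strains:
        if not proteomes[s]:
            gid = "G_FILL"
            pid = f"{s}_{gid}"
            proteomes[s].append((pid, _random_protein(rng, 100)))
            group_members.setdefault(gid, []).append(pid)

    return PangenomeFixture(
        proteomes=proteomes,
        phenotype=phenotype,
        ec_table=ec_table,
        truth_causal_group=truth_causal,
        group_members=group_members,
        causal_group_id=causal_group_id,
        seed=seed,
        presence_p=presence_p,
    )


# ---------------------------------------------------------------------------
# BilR protein family
# ---------------------------------------------------------------------------

DECOY_CYCLE = ("motif", "length", "domain", "evalue")


@dataclass
class BilrFamilyFixture:
    """Clade-1 short/long members plus single-filter-violating decoys."""

    sequences: list[tuple[str, str]]
    truth: dict[str, str]  # clade1_short | clade1_long | decoy
    motif_truth: dict[str, str]
    domain_table: dict[str, list[str]]
    violation: dict[str, str]  # decoy id -> violated filter
    core_span: dict[str, tuple[int, int]]  # 0-based half-open core location
    reference_id: str
    motif_positions: tuple[int, int, int, int]  # 1-based core residue coords
    core_length: int
    seed: int

    def __post_init__(self):
        for pid, label in self.truth.items():
            if label.startswith("clade1") and self.motif_truth[pid] != DEFAULT_MOTIF:
                raise AssertionError("clade-1 members must carry the HGDR motif")
            if label == "decoy" and pid not in self.violation:
                raise AssertionError(f"decoy {pid} lacks a recorded violation")

    def clade1_alignment(self) -> list[tuple[str, str]]:
        """Ungapped core MSA of the clade-1 members (profile-build input)."""
        seqs = dict(self.sequences)
        rows = []
        for pid, label in sorted(self.truth.items()):
            if label.startswith("clade1"):
                a, b = self.core_span[pid]
                rows.append((pid, seqs[pid][a:b]))
        return rows


def generate_bilr_family(
    n_short: int,
    n_long: int,
    n_decoys: int,
    seed: int,
    core_length: int = 373,
    motif_positions: tuple[int, int, int, int] = (164, 165, 166, 167),
    sub_rate: float = 0.03,
    decoy_types: tuple[str, ...] | None = None,
) -> BilrFamilyFixture:
    """BilR family with controlled motif/length/domain truth.

    Clade-1 members share a random ancestral core with HGDR planted at the
    motif positions (substitutions never touch those columns). Long members
    add an N-terminal flavodoxin-like segment and a C-terminal tail and
    carry [PF07992, PF00724]; short members carry [PF00724]. Decoys cycle
    through motif/length/domain/E-value violations (recorded per decoy).
    """
    if n_short + n_long < 2:
        raise ValueError("need at least two clade-1 members to build a profile")
    if n_short < 0 or n_long < 0 or n_decoys < 0:
        raise ValueError("counts cannot be negative")
    rng = np.random.default_rng(seed)
    motif_idx = [p - 1 for p in motif_positions]
    core = list(_random_protein(rng, core_length))
    for i, ch in zip(motif_idx, DEFAULT_MOTIF):
        core[i] = ch
    core = "".join(core)
    frozen = set(motif_idx)

    sequences: list[tuple[str, str]] = []
    truth: dict[str, str] = {}
    motif_truth: dict[str, str] = {}
    domain_table: dict[str, list[str]] = {}
    violation: dict[str, str] = {}
    core_span: dict[str, tuple[int, int]] = {}

    def motif_of(seq: str, offset: int = 0) -> str:
        return "".join(seq[offset + i] for i in motif_idx)

    for i in range(n_short):
        pid = f"short{i + 1:02d}"
        seq = _mutate_protein(rng, core, sub_rate, frozen)
        sequences.append((pid, seq))
        truth[pid] = "clade1_short"
        motif_truth[pid] = motif_of(seq)
        domain_table[pid] = [PF_TIM_BARREL]
        core_span[pid] = (0, core_length)

    n_term, c_term = 180, 60
    for i in range(n_long):
        pid = f"long{i + 1:02d}"
        mid = _mutate_protein(rng, core, sub_rate, frozen)
        seq = _random_protein(rng, n_term) + mid + _random_protein(rng, c_term)
        sequences.append((pid, seq))
        truth[pid] = "clade1_long"
        motif_truth[pid] = motif_of(seq, offset=n_term)
        domain_table[pid] = [PF_FLAVODOXIN, PF_TIM_BARREL]
        core_span[pid] = (n_term, n_term + core_length)

    cycle = decoy_types or DECOY_CYCLE
    mutant_motifs = ("HGAA", "HGAR", "AGDR")
    for i in range(n_decoys):
        pid = f"decoy{i + 1:02d}"
        kind = cycle[i % len(cycle)]
        violation[pid] = kind
        if kind == "motif":
            bad = mutant_motifs[int(rng.integers(0, len(mutant_motifs)))]
            s = list(_mutate_protein(rng, core, sub_rate, frozen))
            for j, ch in zip(motif_idx, bad):
                s[j] = ch
            seq = "".join(s)
            domain_table[pid] = [PF_TIM_BARREL]
            core_span[pid] = (0, core_length)
        elif kind == "length":
            cut = max(motif_idx) + 2  # keep the motif, drop the C-terminal half
            cut = max(cut, int(0.45 * core_length))
            seq = _mutate_protein(rng, core[:cut], sub_rate, frozen)
            domain_table[pid] = [PF_TIM_BARREL]
            core_span[pid] = (0, cut)
        elif kind == "domain":
            seq = _mutate_protein(rng, core, sub_rate, frozen)
            domain_table[pid] = [PF_TIM_BARREL, "PF01266"]
            core_span[pid] = (0, core_length)
        elif kind == "evalue":
            seq = _random_protein(rng, core_length)
            while motif_of(seq) == DEFAULT_MOTIF:  # pragma: no cover
                seq = _random_protein(rng, core_length)
            domain_table[pid] = [PF_TIM_BARREL]
            core_span[pid] = (0, core_length)
        else:
            raise ValueError(f"unknown decoy type {kind!r}")
        sequences.append((pid, seq))
        truth[pid] = "decoy"
        motif_truth[pid] = motif_of(seq)

    reference_id = "short01" if n_short else "long01"
    return BilrFamilyFixture(
        sequences=sequences,
        truth=truth,
        motif_truth=motif_truth,
        domain_table=domain_table,
        violation=violation,
        core_span=core_span,
        reference_id=reference_id,
        motif_positions=motif_positions,
        core_length=core_length,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Metagenome
# ---------------------------------------------------------------------------

@dataclass
class MetagenomeFixture:
    """Shotgun samples with known bilR/host/background read composition."""

    samples: list[tuple[str, ReadSet, int | None, str]]
    gene_refs: list[str]
    host_ref: str
    truth_presence: dict[str, bool]
    truth_gene_fraction: dict[str, float]
    truth_gene_reads: dict[str, int]
    truth_host_reads: dict[str, int]
    seed: int

    def __post_init__(self):
        for sid, frac in self.truth_gene_fraction.items():
            if self.truth_presence[sid] != (frac > 0):
                raise AssertionError("truth_presence must equal gene_fraction > 0")
        for _, reads, _, _ in self.samples:
            if len(reads) and reads.codes.shape[1] == 0:
                raise AssertionError("reads must have positive length")


def generate_metagenome(
    n_samples: int,
    reads_per_sample: int,
    gene_fractions,
    host_fraction: float,
    error_rate: float,
    seed: int,
    read_length: int = 150,
    n_genes: int = 3,
    gene_length: int = 900,
    host_length: int = 5000,
    cohorts=None,
    ages_days=None,
) -> MetagenomeFixture:
    """Shotgun read sets with known per-sample bilR abundance.

    The bilR read count is deterministic — max(1, round(f*N)) when the gene
    fraction f is positive, 0 otherwise — so recorded presence truth is
    exact; the host count is round(host_fraction*N) and the remainder is
    random background. Per-base substitution errors at ``error_rate``;
    qualities are constant Phred-40.
    """
    gene_fractions = list(gene_fractions)
    if len(gene_fractions) != n_samples:
        raise ValueError("gene_fractions length must equal n_samples")
    if not 0 <= host_fraction <= 1:
        raise ValueError("host_fraction must lie in [0, 1]")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must lie in [0, 1)")
    for f in gene_fractions:
        if not 0 <= f <= 1 or f + host_fraction > 1:
            raise ValueError("need 0 <= gene_fraction and gene+host fraction <= 1")
    rng = np.random.default_rng(seed)
    gene_refs = [_random_dna(rng, gene_length) for _ in range(n_genes)]
    host_ref = _random_dna(rng, host_length)
    gene_codes = [encode(g) for g in gene_refs]
    host_codes = encode(host_ref)

    cohorts = list(cohorts) if cohorts is not None else ["other"] * n_samples
    ages = list(ages_days) if ages_days is not None else [None] * n_samples

    window = np.arange(read_length)

    def draw_from(ref_list, n):
        if n == 0:
            return np.zeros((0, read_length), dtype=np.uint8)
        rows = np.empty((n, read_length), dtype=np.uint8)
        which = rng.integers(0, len(ref_list), size=n)
        for g, ref in enumerate(ref_list):
            sel = np.flatnonzero(which == g)
            if sel.size == 0:
                continue
            pos = rng.integers(0, ref.size - read_length + 1, size=sel.size)
            rows[sel] = ref[pos[:, None] + window]
        flip = rng.random(n) < 0.5
        rows[flip] = revcomp_codes(rows[flip])
        return rows

    samples = []
    truth_presence: dict[str, bool] = {}
    truth_gene_fraction: dict[str, float] = {}
    truth_gene_reads: dict[str, int] = {}
    truth_host_reads: dict[str, int] = {}
    for si in range(n_samples):
        sid = f"S{si + 1:03d}"
        f = gene_fractions[si]
        n = reads_per_sample
        n_gene = 0 if f == 0 else max(1, round(f * n))
        n_host = min(round(host_fraction * n), n - n_gene)
        n_bg = n - n_gene - n_host
        blocks = [
            draw_from(gene_codes, n_gene),
            draw_from([host_codes], n_host),
            rng.integers(0, 4, size=(n_bg, read_length), dtype=np.uint8)
            if n_bg
            else np.zeros((0, read_length), dtype=np.uint8),
        ]
        codes = np.concatenate(blocks, axis=0)
        perm = rng.permutation(n)
        codes = codes[perm]
        if error_rate > 0:
            mask = rng.random(codes.shape) < error_rate
            shift = rng.integers(1, 4, size=codes.shape, dtype=np.uint8)
            codes = np.where(mask, (codes + shift) % 4, codes).astype(np.uint8)
        ids = [f"{sid}.r{i:06d}" for i in range(n)]
        samples.append((sid, ReadSet(ids, codes), ages[si], cohorts[si]))
        truth_presence[sid] = f > 0
        truth_gene_fraction[sid] = f
        truth_gene_reads[sid] = n_gene
        truth_host_reads[sid] = n_host

    return MetagenomeFixture(
        samples=samples,
        gene_refs=gene_refs,
        host_ref=host_ref,
        truth_presence=truth_presence,
        truth_gene_fraction=truth_gene_fraction,
        truth_gene_reads=truth_gene_reads,
        truth_host_reads=truth_host_reads,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Fluorescence
# ---------------------------------------------------------------------------

@dataclass
class FluorescenceFixture:
    """Replicate fluorescence tables with known reducer truth."""

    measurements: dict[str, list[float]]
    control_values: list[float]
    truth_reducer: dict[str, bool]
    seed: int

    def __post_init__(self):
        for strain, vals in self.measurements.items():
            if len(vals) < 3:
                raise AssertionError(f"strain {strain} has fewer than 3 replicates")
        if any(v <= 0 for v in self.control_values):
            raise AssertionError("control values must be strictly positive")


def generate_fluorescence(
    strains,
    fold_change: float,
    cv: float,
    n_reps: int = 3,
    seed: int = 0,
    control_mean: float = 1000.0,
    n_control: int = 3,
) -> FluorescenceFixture:
    """Lognormal replicate fluorescence with a known reducer effect size.

    Reducer strains have mean ``fold_change`` times the abiotic control
    mean; non-reducers sit at the control mean. ``strains`` is a list of
    (strain_id, is_reducer) pairs or a dict.
    """
    if fold_change <= 0:
        raise ValueError("fold_change must be positive")
    if n_reps < 3:
        raise ValueError("need at least 3 replicates per strain")
    if cv < 0:
        raise ValueError("coefficient of variation cannot be negative")
    pairs = sorted(strains.items()) if isinstance(strains, dict) else list(strains)
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(cv**2)))

    def draws(mean, n):
        mu_log = np.log(mean) - sigma**2 / 2
        return [float(v) for v in rng.lognormal(mu_log, sigma, size=n)]

    measurements = {}
    truth = {}
    for sid, is_reducer in pairs:
        mean = control_mean * fold_change if is_reducer else control_mean
        measurements[sid] = draws(mean, n_reps)
        truth[sid] = bool(is_reducer)
    control = draws(control_mean, n_control)
    return FluorescenceFixture(
        measurements=measurements,
        control_values=control,
        truth_reducer=truth,
        seed=seed,
    )
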