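"""Fixture persistence: FASTA/FASTQ/TSV on disk plus a JSON truth sidecar.

Each writer lays out one fixture as the plain-text files the pipeline's
readers consume; the recorded ground truth goes to ``truth.json`` so that
written fixtures stay fully self-describing.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import io
from .synthetic import (
    BilrFamilyFixture,
    FluorescenceFixture,
    MetagenomeFixture,
    PangenomeFixture,
)

CONTROL_LABEL = "__control__"


# -- pangenome --------------------------------------------------------------

def write_pangenome(fx: PangenomeFixture, outdir) -> None:
    outdir = Path(outdir)
    for strain, prots in fx.proteomes.items():
        io.write_fasta(prots, outdir / "proteomes" / f"{strain}.fasta")
    io.write_tsv(
        pd.DataFrame(
            [(s, v) for s, v in sorted(fx.phenotype.items())],
            columns=["strain", "label"],
        ),
        outdir / "phenotype.tsv",
    )
    io.write_tsv(
        pd.DataFrame(
            [(p, e) for p, e in sorted(fx.ec_table.items())],
            columns=["protein", "ec"],
        ),
        outdir / "ec.tsv",
    )
    io.write_json(
        {
            "truth_causal_group": sorted(fx.truth_causal_group),
            "causal_group_id": fx.causal_group_id,
            "group_members": {k: sorted(v) for k, v in fx.group_members.items()},
            "seed": fx.seed,
            "presence_p": fx.presence_p,
        },
        outdir / "truth.json",
    )


def load_pangenome(indir):
    """Read a written pangenome back: (proteomes, phenotype, ec_table, truth)."""
    indir = Path(indir)
    proteomes = {
        p.stem: io.read_fasta(p)
        for p in sorted((indir / "proteomes").glob("*.fasta"))
    }
    pheno_df = io.read_tsv(indir / "phenotype.tsv")
    phenotype = dict(zip(pheno_df["strain"], pheno_df["label"]))
    ec_df = io.read_tsv(indir / "ec.tsv")
    ec_table = dict(zip(ec_df["protein"], ec_df["ec"]))
    truth = io.read_json(indir / "truth.json") if (indir / "truth.json").exists() else None
    return proteomes, phenotype, ec_table, truth


# -- protein family ---------------------------------------------------------

def write_family(fx: BilrFamilyFixture, outdir) -> None:
    outdir = Path(outdir)
    io.write_fasta(fx.sequences, outdir / "sequences.fasta")
    io.write_fasta(fx.clade1_alignment(), outdir / "clade1_core_alignment.fasta")
    io.write_tsv(
        pd.DataFrame(
            [(p, ",".join(d)) for p, d in sorted(fx.domain_table.items())],
            columns=["protein", "domains"],
        ),
        outdir / "domains.tsv",
    )
    io.write_json(
        {
            "truth": fx.truth,
            "motif_truth": fx.motif_truth,
            "violation": fx.violation,
            "core_span": {k: list(v) for k, v in fx.core_span.items()},
            "reference_id": fx.reference_id,
            "motif_positions": list(fx.motif_positions),
            "core_length": fx.core_length,
            "seed": fx.seed,
        },
        outdir / "truth.json",
    )


def load_family(indir):
    """Read a written family back: (sequences, domain_table, msa, truth)."""
    indir = Path(indir)
    sequences = io.read_fasta(indir / "sequences.fasta")
    msa = io.read_fasta(indir / "clade1_core_alignment.fasta")
    dom_df = io.read_tsv(indir / "domains.tsv")
    domain_table = {
        p: d.split(",") if d else [] for p, d in zip(dom_df["protein"], dom_df["domains"])
    }
    truth = io.read_json(indir / "truth.json") if (indir / "truth.json").exists() else None
    return sequences, domain_table, msa, truth


# -- metagenome -------------------------------------------------------------

def write_metagenome(fx: MetagenomeFixture, outdir) -> None:
    outdir = Path(outdir)
    rows = []
    for sid, reads, age, cohort in fx.samples:
        io.write_fastq(reads, outdir / "reads" / f"{sid}.fastq")
        rows.append((sid, cohort, "" if age is None else age))
    io.write_fasta(
        [(f"bilR{i + 1:02d}", g) for i, g in enumerate(fx.gene_refs)],
        outdir / "gene_refs.fasta",
    )
    io.write_fasta([("host", fx.host_ref)], outdir / "host.fasta")
    io.write_tsv(
        pd.DataFrame(rows, columns=["sample", "cohort", "age_days"]),
        outdir / "metadata.tsv",
    )
    io.write_json(
        {
            "truth_presence": fx.truth_presence,
            "truth_gene_fraction": fx.truth_gene_fraction,
            "truth_gene_reads": fx.truth_gene_reads,
            "truth_host_reads": fx.truth_host_reads,
            "seed": fx.seed,
        },
        outdir / "truth.json",
    )


def load_metagenome(indir):
    """Read a written metagenome back: (samples, gene_refs, host_ref, truth)."""
    indir = Path(indir)
    meta = io.read_tsv(indir / "metadata.tsv")
    samples = []
    for _, row in meta.iterrows():
        reads = io.read_fastq(indir / "reads" / f"{row['sample']}.fastq")
        age = None if pd.isna(row["age_days"]) or row["age_days"] == "" else int(row["age_days"])
        samples.append((row["sample"], reads, age, row["cohort"]))
    gene_refs = [s for _, s in io.read_fasta(indir / "gene_refs.fasta")]
    host_ref = io.read_fasta(indir / "host.fasta")[0][1]
    truth = io.read_json(indir / "truth.json") if (indir / "truth.json").exists() else None
    return samples, gene_refs, host_ref, truth


# -- fluorescence -----------------------------------------------------------

def write_fluorescence(fx: FluorescenceFixture, outdir) -> None:
    outdir = Path(outdir)
    rows = []
    for strain in sorted(fx.measurements):
        for rep, v in enumerate(fx.measurements[strain], start=1):
            rows.append((strain, rep, v, False))
    for rep, v in enumerate(fx.control_values, start=1):
        rows.append((CONTROL_LABEL, rep, v, True))
    io.write_tsv(
        pd.DataFrame(rows, columns=["strain", "replicate", "value", "is_control"]),
        outdir / "fluorescence.tsv",
    )
    io.write_json(
        {"truth_reducer": fx.truth_reducer, "seed": fx.seed},
        outdir / "truth.json",
    )


def load_fluorescence(indir):
    """Read a written assay table back: (measurements, control_values, truth)."""
    indir = Path(indir)
    df = io.read_tsv(indir / "fluorescence.tsv")
    measurements: dict[str, list[float]] = {}
    control: list[float] = []
    for _, row in df.iterrows():
        if bool(row["is_control"]):
            control.append(float(row["value"]))
        else:
            measurements.setdefault(row["strain"], []).append(float(row["value"]))
    truth = io.read_json(indir / "truth.json") if (indir / "truth.json").exists() else None
    return measurements, control, truth
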