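"""Profile bilR presence in shotgun metagenomes and compare cohorts.

Simulates 20 samples of 50,000 reads (150 bp, 1% substitution error, 20%
host contamination): ten infant samples with no bilR reads, ten adult
samples at a gene fraction giving ~20 bilR counts per million (CPM). Each
sample goes through host-read removal, a read-count QC gate, k-mer
seed-and-extend mapping to the bilR gene set, CPM normalisation, and the
strict CPM > 5 presence call; cohort prevalence is compared with a test of
equal proportions.
"""

from bilrscreen import RunConfig, pipeline, synthetic

fx = synthetic.generate_metagenome(
    n_samples=20,
    reads_per_sample=50_000,
    gene_fractions=[0.0] * 10 + [2e-5] * 10,
    host_fraction=0.2,
    error_rate=0.01,
    seed=11,
    cohorts=["infant"] * 10 + ["healthy_adult"] * 10,
    ages_days=[10] * 10 + [4000] * 10,
)

config = RunConfig(min_reads=10_000)  # QC floor scaled to fixture size
result = pipeline.run_profiling(fx, config=config)

print(f"\n{'sample':<8} {'cohort':<14} {'reads':>7} {'mapped':>7} {'CPM':>7} {'present':>8}")
for p in result.profiles:
    print(
        f"{p.sample_id:<8} {p.cohort:<14} {p.total_reads:>7} {p.mapped_reads:>7}"
        f" {p.cpm:>7.1f} {str(p.present):>8}"
    )

comp = result.prevalence["infant_vs_healthy_adult"]
print(
    f"\nbilR absent in {comp.n_absent[0]}/{comp.n[0]} infants vs "
    f"{comp.n_absent[1]}/{comp.n[1]} adults: "
    f"chi-square = {comp.statistic:.2f}, p = {comp.p_value:.2e}"
)
print("a single mapped read at this depth gives ~25 CPM, above the 5-CPM")
print("presence cut; absent samples map nothing despite host contamination.")
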