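"""Call bilirubin-reducer phenotypes from a fluorescence assay table.

Generates a replicate table for four strains (two true reducers at a
20-fold signal over the abiotic control), then calls each strain with the
strict ratio-above-5 rule and a one-sided Welch t-test on log2 values.
"""

from bilrscreen import assay, synthetic

fx = synthetic.generate_fluorescence(
    [("R. gnavus", True), ("C. symbiosum", True), ("B. fragilis", False), ("E. coli", False)],
    fold_change=20.0,
    cv=0.1,
    seed=1,
)

print(f"{'strain':<14} {'ratio':>7} {'reducer':>8} {'p (log2 t-test)':>16}")
for call in assay.call_table(fx.measurements, fx.control_values):
    print(
        f"{call.strain_id:<14} {call.ratio:>7.2f} {str(call.is_reducer):>8}"
        f" {call.p_value:>16.2e}"
    )
print()
print("ratio = mean strain fluorescence / mean abiotic control; a strain is")
print("called a reducer only when the ratio is strictly above 5.")
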