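"""Profile building, local Viterbi, Gumbel calibration, BilR classification."""

import numpy as np
import pytest
from helpers import brute_force_viterbi, random_small_profile

from bilrscreen import hmm, synthetic
from bilrscreen.hmm import AA, ProfileBuildError


def random_protein(rng, n):
    return "".join(AA[i] for i in rng.integers(0, 20, size=n))


class TestBuildProfile:
    def test_identical_sequences_full_span(self):
        seq = "MKTAYIAKQR"
        msa = [(f"s{i}", seq) for i in range(5)]
        p = hmm.build_profile(msa, "s0")
        assert p.n_match == len(seq)
        assert p.consensus() == seq

    def test_span_restricts_to_reference_residues(self):
        """Only columns holding the reference's first-373-style span survive."""
        rng = np.random.default_rng(0)
        ref = random_protein(rng, 700)
        msa = [("ref", ref)] + [(f"s{i}", random_protein(rng, 700)) for i in range(3)]
        p = hmm.build_profile(msa, "ref", reference_residue_span=(1, 373))
        assert p.n_match == 373
        assert p.reference_length == 700  # full protein length, for the 50% rule

    def test_laplace_pseudocount_emission(self):
        # column with residue counts {A:4, C:1} and +1 smoothing: P(A) = 5/25
        msa = [("s0", "A"), ("s1", "A"), ("s2", "A"), ("s3", "A"), ("s4", "C")]
        p = hmm.build_profile(msa, "s0")
        assert p.match_emissions[0, AA.index("A")] == pytest.approx(5 / 25)
        assert p.match_emissions[0, AA.index("C")] == pytest.approx(2 / 25)
        assert p.match_emissions[0, AA.index("W")] == pytest.approx(1 / 25)

    def test_gappy_column_becomes_insert(self):
        msa = [("ref", "MKT"), ("a", "M-T"), ("b", "M-T"), ("c", "MKT")]
        p = hmm.build_profile(msa, "ref")
        assert p.n_match == 3  # exactly 50% gapped: not *more* than half, kept
        p2 = hmm.build_profile(msa, "ref", max_gap_fraction=0.4)
        assert p2.n_match == 2

    def test_motif_position_must_map_to_match_column(self):
        msa = [("ref", "MKTA" * 3), ("a", "M--" + "A" * 9), ("b", "M--" + "A" * 9)]
        with pytest.raises(ProfileBuildError):
            hmm.build_profile(msa, "ref", motif_reference_positions=(2, 3, 4, 5))

    def test_missing_reference_rejected(self):
        with pytest.raises(ProfileBuildError):
            hmm.build_profile([("a", "MKT")], "nope")


class TestViterbi:
    def test_consensus_aligns_every_column(self, calibrated_profile):
        hit = hmm.viterbi_search(calibrated_profile, calibrated_profile.consensus())
        assert len(hit.column_map) == calibrated_profile.n_match
        assert "-" not in hit.column_map.values()
        assert hit.target_start == 1
        assert hit.target_end == calibrated_profile.n_match

    def test_flanking_sequence_never_decreases_score(self, calibrated_profile):
        rng = np.random.default_rng(1)
        core = calibrated_profile.consensus()
        base = hmm.viterbi_score(calibrated_profile, core)
        embedded = random_protein(rng, 50) + core + random_protein(rng, 50)
        assert hmm.viterbi_score(calibrated_profile, embedded) >= base - 1e-9

    def test_matches_brute_force_enumeration(self):
        """Local Viterbi equals exhaustive path enumeration on 200 instances."""
        rng = np.random.default_rng(99)
        for _ in range(200):
            k = int(rng.integers(1, 6))
            profile = random_small_profile(rng, k)
            target = random_protein(rng, int(rng.integers(1, 7)))
            got = hmm.viterbi_score(profile, target)
            want = brute_force_viterbi(profile, target)
            assert got == want

    def test_traceback_score_is_dp_optimum(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            profile = random_small_profile(rng, int(rng.integers(2, 6)))
            target = random_protein(rng, int(rng.integers(2, 7)))
            hit = hmm.viterbi_search(profile, target, "t")
            assert hit.score == hmm.viterbi_score(profile, target)
            assert 1 <= hit.target_start <= hit.target_end <= len(target)


class TestCalibration:
    def test_same_seed_same_parameters(self, calibrated_profile, family):
        p = hmm.build_profile(
            family.clade1_alignment(), family.reference_id,
            reference_residue_span=(1, family.core_length),
            motif_reference_positions=family.motif_positions,
        )
        again = hmm.calibrate(p, n_random=300, random_length=400, seed=17)
        assert again.mu == calibrated_profile.mu
        assert again.lam == calibrated_profile.lam

    def test_evalue_monotone_decreasing_in_score(self, calibrated_profile):
        scores = np.linspace(-10, 200, 40)
        evals = [hmm.score_to_evalue(s, calibrated_profile, 100) for s in scores]
        assert all(a >= b for a, b in zip(evals, evals[1:]))

    def test_closed_form_at_location(self, calibrated_profile):
        e = hmm.score_to_evalue(calibrated_profile.mu, calibrated_profile, 1)
        assert e == pytest.approx(1 - np.exp(-1), abs=1e-12)

    def test_database_size_scales_linearly(self, calibrated_profile):
        e1 = hmm.score_to_evalue(10.0, calibrated_profile, 100)
        e2 = hmm.score_to_evalue(10.0, calibrated_profile, 200)
        assert e2 == pytest.approx(2 * e1)

    def test_gumbel_parameter_recovery(self):
        from scipy import stats

        draws = stats.gumbel_r.rvs(loc=2.0, scale=1 / 0.7, size=5000, random_state=11)
        mu, lam = hmm.fit_gumbel(draws)
        assert mu == pytest.approx(2.0, abs=0.1)
        assert lam == pytest.approx(0.7, abs=0.05)

    def test_uncalibrated_profile_rejected(self):
        p = random_small_profile(np.random.default_rng(0), 3)
        with pytest.raises(RuntimeError):
            hmm.score_to_evalue(1.0, p, 10)

    def test_small_sample_rejected(self):
        p = random_small_profile(np.random.default_rng(0), 3)
        with pytest.raises(ValueError):
            hmm.calibrate(p, n_random=50, random_length=20, seed=0)


class TestClassify:
    def _calls(self, profile, family, seqs=None, domains=None):
        return hmm.scan_database(
            profile,
            seqs if seqs is not None else dict(family.sequences),
            domains if domains is not None else family.domain_table,
        )

    def test_family_truth_recovered_exactly(self, calibrated_profile, family):
        want = {"clade1_short": "short", "clade1_long": "long", "decoy": "none"}
        calls = self._calls(calibrated_profile, family)
        for c in calls:
            assert c.verdict == want[family.truth[c.target_id]], c

    def test_decoy_audit_names_violated_filter(self, calibrated_profile, family):
        calls = {c.target_id: c for c in self._calls(calibrated_profile, family)}
        for pid, kind in family.violation.items():
            assert getattr(calls[pid], f"{kind}_pass") is False, (pid, kind)

    def test_motif_mutation_rejected(self, calibrated_profile, family):
        """A clade-1 sequence with the catalytic Asp-Arg pair mutated to
        Ala-Ala (HGDR -> HGAA) loses its verdict on the motif filter."""
        seqs = dict(family.sequences)
        pid = family.reference_id
        a, _ = family.core_span[pid]
        idx = [a + p - 1 for p in family.motif_positions]
        s = list(seqs[pid])
        assert "".join(s[i] for i in idx) == "HGDR"
        s[idx[2]], s[idx[3]] = "A", "A"
        mutant = "".join(s)

        ok = self._calls(calibrated_profile, family,
                         seqs={pid: seqs[pid]}, domains=family.domain_table)[0]
        bad = self._calls(calibrated_profile, family,
                          seqs={pid: mutant}, domains=family.domain_table)[0]
        assert ok.verdict != "none" and ok.motif_pass
        assert bad.verdict == "none" and not bad.motif_pass
        assert bad.observed_motif == "HGAA"
        assert bad.evalue_pass and bad.length_pass and bad.domain_pass

    def test_short_length_fails_boundary(self, calibrated_profile, family):
        seqs = dict(family.sequences)
        pid = "short01"
        short = seqs[pid][: int(0.49 * calibrated_profile.reference_length)]
        call = self._calls(calibrated_profile, family, seqs={pid: short})[0]
        assert call.verdict == "none" and not call.length_pass

    def test_unexpected_domains_fail(self, calibrated_profile, family):
        pid = "short01"
        call = self._calls(
            calibrated_profile, family,
            seqs={pid: dict(family.sequences)[pid]},
            domains={pid: ["PF00724", "PF00724", "PF01266"]},
        )[0]
        assert call.verdict == "none" and not call.domain_pass

    def test_missing_annotation_is_audited_not_raised(self, calibrated_profile, family):
        pid = "short01"
        call = self._calls(
            calibrated_profile, family,
            seqs={pid: dict(family.sequences)[pid]}, domains={},
        )[0]
        assert call.verdict == "none"
        assert call.domain_fail_reason == "unannotated"

    def test_threshold_weakening_is_monotone(self, calibrated_profile, family):
        """Relaxing E-value or length thresholds never shrinks the hit set."""
        def nonnone(**kw):
            return {
                c.target_id
                for c in hmm.scan_database(
                    calibrated_profile, dict(family.sequences), family.domain_table, **kw
                )
                if c.verdict != "none"
            }

        strict = nonnone()
        assert strict <= nonnone(evalue_max=1.0)
        assert strict <= nonnone(min_length_fraction=0.1)
        assert strict <= nonnone(evalue_max=1e10, min_length_fraction=0.0)

    def test_scan_is_order_invariant(self, calibrated_profile, family):
        fwd = self._calls(calibrated_profile, family)
        rev = hmm.scan_database(
            calibrated_profile,
            list(reversed(family.sequences)),
            family.domain_table,
        )
        assert {c.target_id: c.verdict for c in fwd} == {
            c.target_id: c.verdict for c in rev
        }


def test_profile_json_round_trip(calibrated_profile):
    d = calibrated_profile.to_dict()
    import json

    back = hmm.ProfileHMM.from_dict(json.loads(json.dumps(d)))
    assert back.mu == calibrated_profile.mu
    assert back.motif_columns == calibrated_profile.motif_columns
    np.testing.assert_array_equal(back.match_emissions, calibrated_profile.match_emissions)
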