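import numpy as np
import pytest

from tmodscan import (AlignmentRecord, ModificationProfile, build_position_table,
                      call_modifications, estimate_modified_fraction,
                      flag_lower_bound, modification_index)
from helpers import simulate_align_pileup


def _full_record(read_id, ref, start=1, mismatches=()):
    return AlignmentRecord(
        read_id=read_id, ref_name=ref.name, start=start, end=ref.mature_len,
        n_mismatch=len(mismatches), mismatch_list=tuple(mismatches),
        orientation="antisense", unique=True,
    )


class TestModificationIndex:
    def test_printed_worked_example(self):
        # mutation 0.074 + stop 0.086 at an m1A site
        assert modification_index(0.086, 0.074) == pytest.approx(0.16)

    def test_zero(self):
        assert modification_index(0.0, 0.0) == 0.0

    def test_shared_denominator_violation_is_an_error(self):
        with pytest.raises(ValueError, match="denominator"):
            modification_index(0.7, 0.4)

    def test_inputs_must_be_fractions(self):
        with pytest.raises(ValueError):
            modification_index(-0.1, 0.2)
        with pytest.raises(ValueError):
            modification_index(0.1, 1.2)


class TestPositionTable:
    def test_hand_counted_fixture(self, refset, mt_tk):
        """10 reads reach the site: 2 stop at 40, 1 of 8 read-throughs mutated."""
        p = 40
        other = "G" if mt_tk.mature_seq[p - 1] != "G" else "T"
        records = (
            [_full_record(f"s{i}", mt_tk, start=p + 1) for i in range(2)]
            + [_full_record(f"r{i}", mt_tk) for i in range(7)]
            + [_full_record("m0", mt_tk,
                            mismatches=[(p, mt_tk.mature_seq[p - 1], other)])]
        )
        table = build_position_table(records, refset, min_coverage=5)["MT-TK"]
        row = table.row(p)
        assert row["N"] == 10 and row["S"] == 2 and row["R"] == 8 and row["X"] == 1
        assert row["stop_frac"] == pytest.approx(0.2)
        assert row["mut_frac"] == pytest.approx(0.1)
        assert row["MI"] == pytest.approx(0.3)

    def test_all_full_length_clean_reads_give_zero_mi(self, refset, mt_tk):
        records = [_full_record(f"r{i}", mt_tk) for i in range(60)]
        table = build_position_table(records, refset)["MT-TK"]
        assert (table.table["MI"].to_numpy() == 0).all()
        assert table.full_length_count == 60

    def test_conservation_invariant_on_simulation(self, refset):
        out = simulate_align_pileup(
            refset, reads_per_ref={"MT-TK": 800}, seq_error_rate=0.0, rng_seed=31,
            profiles=[ModificationProfile("MT-TK", 30, 0.6, 0.5, 0.5),
                      ModificationProfile("MT-TK", 45, 0.3, 0.4, 0.3)])
        table = out["tables"]["MT-TK"]
        assert table.table["S"].sum() + table.full_length_count == table.n_reads == 800

    def test_mi_bounded_and_s_plus_r_equals_n(self, refset):
        out = simulate_align_pileup(
            refset, reads_per_ref={"MT-TK": 600}, seq_error_rate=0.01, rng_seed=37,
            cca_absent_fraction=0.3, oligoA_mean_cca_absent=2.0,
            profiles=[ModificationProfile("MT-TK", 25, 0.7, 0.5, 0.5)])
        t = out["tables"]["MT-TK"].table
        covered = t[t["N"] > 0]
        assert ((covered["MI"] >= 0) & (covered["MI"] <= 1)).all()
        assert (t["S"] + t["R"] == t["N"]).all()

    def test_unknown_reference_rejected(self, refset, mt_tk):
        rec = AlignmentRecord(read_id="r", ref_name="NOPE", start=1, end=73,
                              n_mismatch=0, mismatch_list=(), orientation="sense",
                              unique=True)
        with pytest.raises(ValueError, match="NOPE"):
            build_position_table([rec], refset)

    def test_two_peak_signature_of_template_methyl(self, refset):
        """A methyl at q: the mutation peak sits at q, the raw cDNA
        5'-terminus peak one position 3' of it (the stop-before-copy read
        starts at q+1)."""
        q = 9
        out = simulate_align_pileup(
            refset, reads_per_ref={"MT-TK": 2000}, seq_error_rate=0.0, rng_seed=41,
            profiles=[ModificationProfile("MT-TK", q, 1.0, 0.5, 0.5)])
        starts = np.zeros(80, dtype=int)
        for rec in out["records"]:
            if rec.start > 1:
                starts[rec.start] += 1
        assert starts.argmax() == q + 1
        t = out["tables"]["MT-TK"].table
        assert t.loc[t["X"].idxmax(), "pos"] == q


class TestLowerBoundFlag:
    def test_default_threshold(self, refset):
        out = simulate_align_pileup(refset, reads_per_ref={"MT-TK": 80},
                                    seq_error_rate=0.0, rng_seed=43)
        table = out["tables"]["MT-TK"]
        # Lys m1A58 site: 19 nt from the 3' end -> flagged
        assert bool(table.row(54)["lower_bound"])
        assert not bool(table.row(33)["lower_bound"])  # 40 nt away

    def test_threshold_zero_flags_nothing(self, refset):
        out = simulate_align_pileup(refset, reads_per_ref={"MT-TK": 50},
                                    seq_error_rate=0.0, rng_seed=47)
        table = flag_lower_bound(out["tables"]["MT-TK"], refset, threshold=0)
        assert not table.table["lower_bound"].any()


@pytest.fixture(scope="module")
def matched_tables(refset):
    profiles = [
        ModificationProfile("MT-TK", 20, 0.9, 0.45, 0.45,
                            demethylase_sensitive=True),
        ModificationProfile("MT-TK", 34, 0.8, 0.0, 0.25,
                            demethylase_sensitive=False),
    ]
    kw = dict(reads_per_ref={"MT-TK": 4000}, seq_error_rate=0.001,
              profiles=profiles)
    untreated = simulate_align_pileup(refset, rng_seed=53, **kw)["tables"]
    treated = simulate_align_pileup(refset, rng_seed=59,
                                    demethylase_treated=True, **kw)["tables"]
    return untreated, treated


class TestCallModifications:
    def test_methyl_and_non_methyl_calls(self, refset, matched_tables):
        untreated, treated = matched_tables
        calls = call_modifications(untreated, treated, refset)
        by_pos = calls[calls["ref"] == "MT-TK"].set_index("pos")["call"]
        assert by_pos.loc[20] == "demethylase_sensitive_methyl"
        assert by_pos.loc[34] == "non_methyl_signal"
        assert by_pos.loc[25] == "unmodified"  # background error only

    def test_mismatched_references_rejected(self, refset, matched_tables):
        untreated, treated = matched_tables
        partial = {k: v for k, v in treated.items() if k != "MT-TK"}
        with pytest.raises(ValueError, match="different references"):
            call_modifications(untreated, partial, refset)


class TestEstimateModifiedFraction:
    def test_printed_worked_example(self):
        assert estimate_modified_fraction(0.24, 0.5) == pytest.approx(0.48)

    def test_share_one_is_identity(self):
        assert estimate_modified_fraction(0.37, 1.0) == pytest.approx(0.37)

    def test_empirical_share_variant(self):
        # the context-matched empirical mutation share 0.074/0.16
        est = estimate_modified_fraction(0.24, 0.074 / 0.16)
        assert est == pytest.approx(0.519, abs=5e-4)

    def test_cap_warns(self):
        with pytest.warns(UserWarning, match="capping"):
            assert estimate_modified_fraction(0.9, 0.5) == 1.0

    def test_bad_share_rejected(self):
        with pytest.raises(ValueError):
            estimate_modified_fraction(0.2, 0.0)
        with pytest.raises(ValueError):
            estimate_modified_fraction(1.2, 0.5)
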