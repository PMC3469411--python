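"""Spectrum IO, class counting, rate partitioning and hotspot detection."""

import numpy as np
import pytest

from strandmmr import spectra as sp
from strandmmr.errors import ValidationError
from strandmmr.reporter import MutationKind, MutationRecord, Orientation
from strandmmr.simulate import build_error_model, default_design, simulate_study

from .conftest import make_indel, make_spectrum, make_substitution


@pytest.fixture
def mixed_spectrum(locus_or1):
    """3 substitutions (2 at site 686), 1 deletion, 1 insertion, 1 multibase."""
    records = [
        make_substitution(locus_or1, 686, "T", mutant_id="m1"),
        make_substitution(locus_or1, 686, "T", mutant_id="m2"),
        make_substitution(locus_or1, 279, "G", mutant_id="m3"),
        make_indel(locus_or1, 177, MutationKind.DELETION, mutant_id="m4"),
        make_indel(locus_or1, 255, MutationKind.INSERTION, base="A", mutant_id="m5"),
        MutationRecord("m6", 10, MutationKind.MULTIBASE, strain="s"),
    ]
    return make_spectrum(records, n_sequenced=10, n_no_orf_change=2)


class TestSpectrumIO:
    def test_round_trip_identity(self, mixed_spectrum, locus_or1, tmp_path):
        path = tmp_path / "spec.tsv"
        sp.write_spectrum(mixed_spectrum, path)
        back = sp.read_spectrum(path, locus_or1)
        assert back == mixed_spectrum

    def test_bad_ref_reported_with_line_number(self, locus_or1, tmp_path):
        path = tmp_path / "bad.tsv"
        lines = [
            "# n_sequenced=5",
            "mutant_id\tstrain\tmmr_status\torientation\tposition\tkind\tref\talt",
            "m1\ts\tproficient\tOR1\t686\tsubstitution\tA\tT",
            "m2\ts\tproficient\tOR1\t686\tsubstitution\tC\tT",  # ref is A
        ]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValidationError, match=r"line 4.*position 686"):
            sp.read_spectrum(path, locus_or1)

    def test_multibase_rows_parsed_but_excluded_from_counts(
        self, mixed_spectrum, locus_or1, tmp_path
    ):
        path = tmp_path / "spec.tsv"
        sp.write_spectrum(mixed_spectrum, path)
        back = sp.read_spectrum(path, locus_or1)
        assert back.n_multibase == 1
        assert sp.count_class(back, sp.all_single_base(), locus_or1) == 5

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "short.tsv"
        path.write_text("mutant_id\tposition\nm1\t4\n")
        with pytest.raises(ValidationError, match="missing columns"):
            sp.read_spectrum(path)


class TestCountClass:
    def test_selector_counts(self, mixed_spectrum, locus_or1):
        cases = {
            "all_single_base": 5,
            "substitution": 3,
            "transversion": 2,  # A>T x2
            "transition": 1,  # A>G
            "single_deletion": 1,
            "single_insertion": 1,
        }
        for sel in sp.standard_selectors():
            assert sp.count_class(mixed_spectrum, sel, locus_or1) == cases[sel.name]

    def test_site_selector_counts_two_hits_at_686(self, mixed_spectrum, locus_or1):
        assert sp.count_class(mixed_spectrum, sp.site(686), locus_or1) == 2
        assert (
            sp.count_class(
                mixed_spectrum, sp.site_and_change(686, "A", "T"), locus_or1
            )
            == 2
        )

    def test_transitions_and_transversions_partition_substitutions(
        self, locus_or1
    ):
        model = build_error_model()
        design = default_design(seed=3, orientations=(Orientation.OR1,))
        ds = simulate_study(model, design)
        spectrum = next(iter(ds.spectra.values()))
        n_ts = sp.count_class(spectrum, sp.transitions(), locus_or1)
        n_tv = sp.count_class(spectrum, sp.transversions(), locus_or1)
        n_sub = sp.count_class(spectrum, sp.substitutions(), locus_or1)
        assert n_ts + n_tv == n_sub

    def test_mismatch_selector_groups_complementary_sites(self, locus_or1):
        """A T-dT selector under the leading role picks up coding A->T."""
        spectrum = make_spectrum(
            [make_substitution(locus_or1, 686, "T"),
             make_substitution(locus_or1, 279, "T", mutant_id="m2"),
             make_substitution(locus_or1, 279, "G", mutant_id="m3")]
        )
        sel = sp.inferred_mismatch_class("T-dT", "leading")
        assert sp.count_class(spectrum, sel, locus_or1) == 2

    def test_indel_counts_invariant_to_placement_in_run(self, locus_or1):
        placements = [
            make_spectrum([make_indel(locus_or1, pos, MutationKind.DELETION)])
            for pos in (255, 257, 260)
        ]
        counts = {
            sp.count_class(s, sp.site(255), locus_or1) for s in placements
        }
        assert counts == {1}


class TestPartitionRate:
    def test_arithmetic(self, locus_or1):
        spectrum = make_spectrum(
            [make_substitution(locus_or1, 686, "T", mutant_id=f"m{i}")
             for i in range(20)],
            n_sequenced=100,
        )
        cr = sp.partition_rate(1e-5, spectrum, sp.all_single_base(), locus_or1)
        assert cr.rate == pytest.approx(2e-6)
        assert not cr.zero_count

    def test_zero_count_flagged(self, mixed_spectrum, locus_or1):
        cr = sp.partition_rate(
            1e-5, mixed_spectrum, sp.site(500), locus_or1
        )
        assert cr.rate == 0.0 and cr.zero_count
        assert cr.unit_rate == pytest.approx(1e-5 / 10)

    def test_partition_conserves_total(self, mixed_spectrum, locus_or1):
        """Substitution + insertion + deletion rates sum to the classified
        fraction of the total rate."""
        total = 1e-5
        parts = [
            sp.partition_rate(total, mixed_spectrum, sel, locus_or1)
            for sel in (sp.substitutions(), sp.single_insertions(),
                        sp.single_deletions())
        ]
        classified = sum(p.rate for p in parts)
        assert classified == pytest.approx(total * 5 / 10)

    def test_linear_in_total_rate_and_monotone_in_count(self, locus_or1):
        spectrum = make_spectrum(
            [make_substitution(locus_or1, 686, "T", mutant_id=f"m{i}")
             for i in range(7)],
            n_sequenced=50,
        )
        r1 = sp.partition_rate(1e-6, spectrum, sp.all_single_base(), locus_or1)
        r2 = sp.partition_rate(3e-6, spectrum, sp.all_single_base(), locus_or1)
        assert r2.rate == pytest.approx(3 * r1.rate)
        smaller = sp.partition_rate(1e-6, spectrum, sp.site(686), locus_or1)
        assert smaller.rate <= r1.rate

    def test_denominator_convention_switch(self, mixed_spectrum, locus_or1):
        with_noc = sp.partition_rate(
            1e-5, mixed_spectrum, sp.all_single_base(), locus_or1
        )
        without = sp.partition_rate(
            1e-5, mixed_spectrum, sp.all_single_base(), locus_or1,
            include_no_orf_change=False,
        )
        assert with_noc.denominator == 10 and without.denominator == 8
        assert without.rate > with_noc.rate

    def test_empty_denominator_rejected(self, locus_or1):
        spectrum = make_spectrum([], n_sequenced=0)
        with pytest.raises(ValidationError):
            sp.partition_rate(1e-5, spectrum, sp.all_single_base(), locus_or1)


class TestHotspotScan:
    def test_extreme_enrichment_reported_first(self, locus_or1):
        records = [
            make_substitution(locus_or1, 686, "T", mutant_id=f"h{i}")
            for i in range(30)
        ] + [
            make_substitution(
                locus_or1, 20 + 5 * i, {"A": "T", "C": "A", "G": "T", "T": "A"}[
                    locus_or1.base(20 + 5 * i)
                ], mutant_id=f"b{i}",
            )
            for i in range(30)
        ]
        spectrum = make_spectrum(records, n_sequenced=60)
        hits = sp.hotspot_scan(spectrum, locus_or1)
        assert hits and hits[0][0] == 686 and hits[0][1] == 30

    def test_uniform_spectra_rarely_flag_hotspots(self, locus_or1):
        """Calibration: 200 uniformly spread records should produce no
        Bonferroni-significant site in at least 95% of replicates."""
        rng = np.random.default_rng(20121011)
        false_positive = 0
        n_rep = 60
        for _ in range(n_rep):
            positions = rng.integers(1, 805, size=200)
            records = [
                make_substitution(
                    locus_or1, int(p),
                    {"A": "G", "C": "T", "G": "A", "T": "C"}[locus_or1.base(int(p))],
                    mutant_id=f"r{i}",
                )
                for i, p in enumerate(positions)
            ]
            if sp.hotspot_scan(make_spectrum(records), locus_or1):
                false_positive += 1
        assert false_positive <= 0.05 * n_rep

    def test_generator_hotspot_recovered(self, locus_or1):
        """A 20x engineered hotspot at 279 is detected in the deficient
        spectrum of a study simulated with that configuration."""
        config = {
            "hotspots": [
                {"position": 279, "change": "A>T", "multiplier": 20.0,
                 "orientations": ["OR1"], "efficiency": 1 - 1 / 41.0},
                {"position": 686, "change": "A>T", "multiplier": 20.0,
                 "orientations": ["OR1"], "efficiency": 1 - 1 / 35.0},
            ]
        }
        model = build_error_model(config)
        design = default_design(seed=8, orientations=(Orientation.OR1,))
        ds = simulate_study(model, design)
        spectrum = ds.spectra["pol2-M644G_msh2_OR1"]
        hits = sp.hotspot_scan(spectrum, locus_or1)
        assert 279 in {pos for pos, _, _ in hits}
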