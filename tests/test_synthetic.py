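"""Generator contracts: planted programs, shapes, determinism, NB means."""

import numpy as np
import pandas as pd
import pytest

from cafattract import make_transition_spec
from cafattract.synthetic import (
    PLANTED_LNCRNA,
    SampleProfile,
    TDistribution,
    analytic_mean,
    generate_bulk_cohort,
    generate_cohort,
    generate_sample,
    normal_profile,
    write_cohort,
)


class TestSpecConstruction:
    def test_default_programs_contain_canonical_genes(self, spec):
        by_name = {p.name: p for p in spec.programs}
        assert {"APOD", "CFD"} <= set(by_name["ASC"].genes)
        assert {"COL11A1", "THBS2"} <= set(by_name["CAF"].genes)
        assert {"SFRP4", "RARRES1"} == set(by_name["TRANSIENT"].genes)
        assert "LUM" in by_name["PAN_FIBRO"].genes

    def test_background_override(self):
        spec = make_transition_spec({"n_background_genes": 0})
        program_genes = {g for p in spec.programs for g in p.genes}
        assert set(spec.all_genes) == program_genes

    def test_col11a1_delay(self, spec):
        caf = next(p for p in spec.programs if p.name == "CAF")
        assert spec.effective_t0(caf, "COL11A1") > caf.t0
        flat = make_transition_spec({"col11a1_delay": 0.0})
        caf_flat = next(p for p in flat.programs if p.name == "CAF")
        assert flat.effective_t0(caf_flat, "COL11A1") == caf_flat.t0

    def test_unknown_override_rejected(self):
        with pytest.raises(KeyError):
            make_transition_spec({"not_a_field": 1})

    def test_deterministic(self):
        assert make_transition_spec() == make_transition_spec()


class TestShapes:
    def test_monotone_on_grid(self, spec):
        t = np.linspace(0, 1, 101)
        for prog in spec.programs:
            for gene in prog.genes:
                curve = analytic_mean(spec, gene, t)
                if prog.shape == "decreasing":
                    assert np.all(np.diff(curve) <= 1e-9), gene
                elif prog.shape == "increasing" and prog.compartment == "fibroblast":
                    assert np.all(np.diff(curve) >= -1e-9), gene

    def test_bell_unimodal(self, spec):
        t = np.linspace(0, 1, 101)
        curve = analytic_mean(spec, "SFRP4", t)
        peak = np.argmax(curve)
        assert np.all(np.diff(curve[: peak + 1]) >= -1e-9)
        assert np.all(np.diff(curve[peak:]) <= 1e-9)


class TestGenerateSample:
    def test_point_mass_extremes(self, spec):
        asc = next(p for p in spec.programs if p.name == "ASC").genes
        caf = next(p for p in spec.programs if p.name == "CAF").genes

        def mean_of(genes, matrix):
            idx = [matrix.genes.get_loc(g) for g in genes]
            return matrix.counts[idx].mean()

        low, _ = generate_sample(
            spec,
            SampleProfile(sample="s", t_distribution=TDistribution("point", mean=0.0)),
            seed=1,
        )
        high, _ = generate_sample(
            spec,
            SampleProfile(sample="s", t_distribution=TDistribution("point", mean=1.0)),
            seed=1,
        )
        assert mean_of(asc, low) > mean_of(caf, low)
        assert mean_of(caf, high) > mean_of(asc, high)
        # COL11A1 stays near baseline in the pre-transition sample
        col = low.counts[low.genes.get_loc("COL11A1")].mean()
        assert col < 1.0

    def test_transient_peaks_mid_transition(self, spec):
        profile = SampleProfile(
            sample="u",
            n_fibroblasts=4000,
            n_pericytes=0,
            n_epithelial=0,
            t_distribution=TDistribution("uniform", low=0.0, high=1.0),
        )
        matrix, truth = generate_sample(spec, profile, seed=5)
        sfrp4 = matrix.counts[matrix.genes.get_loc("SFRP4")]
        t = truth["t"].to_numpy()
        windows = {
            "mid": (t >= 0.4) & (t <= 0.6),
            "early": t <= 0.1,
            "late": t >= 0.9,
        }
        observed = {k: sfrp4[w].mean() for k, w in windows.items()}
        assert observed["mid"] > observed["early"]
        assert observed["mid"] > observed["late"]
        # empirical window means track the analytic bell averaged over the
        # same latent coordinates
        for key, w in windows.items():
            predicted = analytic_mean(spec, "SFRP4", t[w]).mean()
            assert observed[key] == pytest.approx(predicted, rel=0.2), key

    def test_empirical_means_match_analytic(self, spec):
        profile = SampleProfile(
            sample="fix",
            n_fibroblasts=5000,
            n_pericytes=0,
            n_epithelial=0,
            t_distribution=TDistribution("point", mean=0.2),
        )
        matrix, _ = generate_sample(spec, profile, seed=9)
        for gene in matrix.genes:
            predicted = analytic_mean(spec, gene, np.array([0.2]))[0]
            if predicted >= 1.0:
                observed = matrix.counts[matrix.genes.get_loc(gene)].mean()
                assert observed == pytest.approx(predicted, rel=0.05), gene

    def test_identical_seed_identical_output(self, spec):
        profile = normal_profile("N1")
        a, ta = generate_sample(spec, profile, seed=3)
        b, tb = generate_sample(spec, profile, seed=3)
        assert np.array_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(ta, tb)

    def test_empty_profile_rejected(self, spec):
        profile = SampleProfile(
            sample="e", n_fibroblasts=0, n_pericytes=0, n_epithelial=0
        )
        with pytest.raises(ValueError):
            generate_sample(spec, profile, seed=0)

    def test_invalid_t_distribution(self):
        with pytest.raises(ValueError):
            TDistribution(kind="point", mean=1.5)
        with pytest.raises(ValueError):
            TDistribution(kind="uniform", low=0.5, high=0.2)


class TestGenerateCohort:
    def test_bookkeeping_and_determinism(self, spec):
        profiles = [
            normal_profile(f"N{i}", n_fibroblasts=60, n_pericytes=20, n_epithelial=20)
            for i in range(3)
        ]
        a = generate_cohort(spec, profiles, seed=4)
        b = generate_cohort(spec, profiles, seed=4)
        assert [m.sample for m, _ in a] == ["N0", "N1", "N2"]
        for (ma, _), (mb, _) in zip(a, b):
            assert np.array_equal(ma.counts, mb.counts)

    def test_different_master_seed_changes_counts(self, spec):
        profiles = [normal_profile("N0", 60, 20, 20)]
        a = generate_cohort(spec, profiles, seed=4)[0][0]
        b = generate_cohort(spec, profiles, seed=5)[0][0]
        assert not np.array_equal(a.counts, b.counts)

    def test_duplicate_ids_rejected(self, spec):
        profiles = [normal_profile("X"), normal_profile("X")]
        with pytest.raises(ValueError):
            generate_cohort(spec, profiles, seed=0)

    def test_ground_truth_round_trips(self, spec, tmp_path):
        profiles = [normal_profile("N0", 50, 15, 15)]
        cohort = generate_cohort(spec, profiles, seed=6)
        write_cohort(cohort, tmp_path, spec)
        back = pd.read_csv(tmp_path / "ground_truth.tsv", sep="\t")
        original = cohort[0][1].reset_index(drop=True)
        pd.testing.assert_frame_equal(
            back, original, check_dtype=False, check_exact=False, rtol=1e-12
        )
        assert (tmp_path / "spec.yaml").exists()


class TestBulkCohort:
    def test_planted_lncrna_tracks_col11a1(self, spec):
        cohort = generate_bulk_cohort(
            spec, n_types=2, caf_positive_fraction=0.5, n_samples_per_type=80, seed=8
        )
        positive = cohort[0]
        log = np.log2(positive.counts + 1)
        target = log[positive.genes.get_loc("COL11A1")]
        planted = np.corrcoef(target, log[positive.genes.get_loc(PLANTED_LNCRNA)])[0, 1]
        random_nc = np.corrcoef(target, log[positive.genes.get_loc("LNC0003")])[0, 1]
        assert planted > 0.3
        assert planted > random_nc

    def test_biotypes_attached(self, spec):
        cohort = generate_bulk_cohort(spec, n_types=2, n_samples_per_type=10, seed=1)
        bt = cohort[0].gene_annotation["biotype"]
        assert set(bt.unique()) == {"coding", "lncRNA", "miRNA"}

    def test_degenerate_inputs_rejected(self, spec):
        with pytest.raises(ValueError):
            generate_bulk_cohort(spec, n_types=1)
        with pytest.raises(ValueError):
            generate_bulk_cohort(spec, caf_positive_fraction=1.5)
        with pytest.raises(ValueError):
            generate_bulk_cohort(spec, n_samples_per_type=1)
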