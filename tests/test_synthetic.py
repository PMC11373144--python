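"""The synthetic-data generator: contracts, determinism, round-trips."""

import numpy as np
import pandas as pd
import pytest

from promsplice.synthetic_data import (
    SimConfig,
    generate_dataset,
    generate_knockdown,
    read_bundle,
    write_bundle,
)

SMALL = dict(n_genes=30, n_tissues=5, n_tfs=8, n_causal_tfs=2)


class TestConfigValidation:
    def test_rejects_nonpositive_counts(self):
        with pytest.raises(ValueError):
            SimConfig(n_genes=0)

    def test_rejects_bad_probability(self):
        with pytest.raises(ValueError):
            SimConfig(occupancy_conservation=1.5)

    def test_rejects_causal_exceeding_total(self):
        with pytest.raises(ValueError):
            SimConfig(n_tfs=5, n_causal_tfs=6)

    def test_rejects_fewer_than_three_tissues(self):
        with pytest.raises(ValueError):
            SimConfig(n_tissues=2)


class TestGenerateDataset:
    def test_same_seed_gives_identical_bundles(self):
        a = generate_dataset(SimConfig(seed=4, **SMALL))
        b = generate_dataset(SimConfig(seed=4, **SMALL))
        assert a.promoter_sequences == b.promoter_sequences
        pd.testing.assert_frame_equal(a.psi, b.psi)
        pd.testing.assert_frame_equal(a.tpm, b.tpm)
        assert a.peaks == b.peaks
        assert a.truth["causal_tfs"] == b.truth["causal_tfs"]

    def test_different_seed_differs(self):
        a = generate_dataset(SimConfig(seed=4, **SMALL))
        b = generate_dataset(SimConfig(seed=5, **SMALL))
        assert a.promoter_sequences != b.promoter_sequences

    def test_psi_bimodality(self):
        bundle = generate_dataset(SimConfig(n_genes=400, n_tissues=10, n_tfs=20,
                                            n_causal_tfs=3, seed=0))
        psi = bundle.psi.values
        middle = np.nanmean((psi > 0.2) & (psi < 0.8))
        assert middle < 0.15

    def test_psi_bounds_and_missingness(self):
        bundle = generate_dataset(SimConfig(seed=1, **SMALL))
        vals = bundle.psi.values
        obs = vals[~np.isnan(vals)]
        assert ((obs >= 0) & (obs <= 1)).all()
        assert np.isnan(vals).any()

    def test_singletons_observed_in_exactly_one_tissue(self):
        bundle = generate_dataset(
            SimConfig(n_genes=100, n_tissues=8, n_tfs=10, n_causal_tfs=2,
                      singleton_fraction=0.2, seed=2)
        )
        singles = bundle.truth["singletons"]
        assert len(singles) == 20
        n_obs = bundle.psi.loc[singles].notna().sum(axis=1)
        assert (n_obs == 1).all()

    def test_truth_tfs_subset_of_tf_set(self):
        bundle = generate_dataset(SimConfig(seed=3, **SMALL))
        assert set(bundle.truth["causal_tfs"]) <= set(bundle.tf_ids)

    def test_every_gene_has_tss_and_strand(self):
        bundle = generate_dataset(SimConfig(seed=3, **SMALL))
        assert bundle.genes.strand.isin(["+", "-"]).all()
        assert (bundle.genes.tss > 0).all()

    def test_occupancy_conservation_one_means_identical_peaks(self):
        bundle = generate_dataset(
            SimConfig(seed=5, occupancy_conservation=1.0, **SMALL)
        )
        tissues = bundle.tissues
        for g in bundle.genes.index:
            first = bundle.peaks[tissues[0]][g]
            assert all(bundle.peaks[t][g] == first for t in tissues[1:])

    def test_null_effect_leaves_association_flat(self):
        from promsplice import pipeline

        bundle = generate_dataset(
            SimConfig(n_genes=250, n_tissues=8, n_tfs=12, n_causal_tfs=3,
                      effect_size=0.0, seed=6)
        )
        events, _ = pipeline.delta_events(bundle)
        events = pipeline.subsample_one_event_per_gene(events, seed=6)
        res = pipeline.delta_association(events, sorted(bundle.tf_ids))
        ors = res.loc[res.valid & res.index.isin(bundle.truth["causal_tfs"]), "odds_ratio"]
        assert np.all(np.abs(np.log2(ors)) < 1.5)  # OR ~ 1 within sampling error


class TestKnockdown:
    def _bundle(self):
        return generate_dataset(SimConfig(n_genes=80, n_tissues=6, n_tfs=10,
                                          n_causal_tfs=2, seed=7))

    def test_nontargets_bitwise_unchanged_without_noise(self):
        bundle = self._bundle()
        sites = bundle.truth["sites"]
        tf = sites.tf.value_counts().index[0]
        kd = generate_knockdown(bundle, tf, shift=1.0, noise_sd=0.0)
        targets = set(kd.truth["knockdown"]["targets"])
        nontargets = [g for g in bundle.psi.index if g not in targets]
        pd.testing.assert_frame_equal(
            bundle.psi.loc[nontargets], kd.psi.loc[nontargets]
        )

    def test_targets_moved_by_shift_in_z_units(self):
        from promsplice import pipeline

        bundle = self._bundle()
        tf = bundle.truth["sites"].tf.value_counts().index[0]
        kd = generate_knockdown(bundle, tf, shift=1.2, noise_sd=0.0)
        dz = pipeline.knockdown_delta_z(bundle, kd)
        targets = set(kd.truth["knockdown"]["targets"])
        on = dz[dz.index.isin(targets)]
        off = dz[~dz.index.isin(targets)]
        # clipping at the PSI boundary can shave a little off the nominal move
        assert on.mean() == pytest.approx(1.2, rel=0.15)
        assert off.max() == pytest.approx(0.0, abs=1e-12)

    def test_zero_shift_null_is_exchangeable(self):
        from promsplice import pipeline
        from promsplice.importance import knockdown_shift_test

        bundle = self._bundle()
        tf = bundle.truth["sites"].tf.value_counts().index[0]
        pvals = []
        for s in range(6):
            kd = generate_knockdown(bundle, tf, shift=0.0, seed=100 + s)
            dz = pipeline.knockdown_delta_z(bundle, kd)
            targets = set(kd.truth["knockdown"]["targets"])
            res = knockdown_shift_test(
                dz[dz.index.isin(targets)].values,
                dz[~dz.index.isin(targets)].values,
            )
            pvals.append(res.pvalue)
        # no systematic signal: p-values spread over (0, 1)
        assert min(pvals) > 1e-4
        assert max(pvals) > 0.2

    def test_tf_without_targets_rejected(self):
        bundle = self._bundle()
        with pytest.raises(ValueError):
            generate_knockdown(bundle, "NOT_A_TF", shift=1.0)


class TestRoundTrip:
    def test_write_then_read_equal_bundle(self, tmp_path):
        bundle = generate_dataset(SimConfig(seed=9, **SMALL))
        write_bundle(bundle, tmp_path)
        back = read_bundle(tmp_path)
        assert back.promoter_sequences == bundle.promoter_sequences
        pd.testing.assert_frame_equal(back.psi, bundle.psi, atol=1e-6)
        pd.testing.assert_frame_equal(back.tpm, bundle.tpm, atol=1e-6)
        assert back.peaks == bundle.peaks
        assert [p.id for p in back.pwms] == [p.id for p in bundle.pwms]
        assert np.allclose(back.pwms[0].counts, bundle.pwms[0].counts)
        assert back.truth["causal_tfs"] == bundle.truth["causal_tfs"]

    def test_bed_intervals_valid(self, tmp_path):
        bundle = generate_dataset(SimConfig(seed=9, **SMALL))
        write_bundle(bundle, tmp_path)
        for bed in (tmp_path / "peaks").glob("*.bed"):
            text = bed.read_text()
            for line in filter(None, text.split("\n")):
                _, start, end = line.split("\t")
                assert 0 <= int(start) < int(end)

    def test_empty_peak_set_writes_valid_empty_bed(self, tmp_path):
        bundle = generate_dataset(SimConfig(seed=9, **SMALL))
        tissue = bundle.tissues[0]
        bundle.peaks[tissue] = {g: [] for g in bundle.genes.index}
        write_bundle(bundle, tmp_path)
        assert (tmp_path / "peaks" / f"{tissue}.bed").read_text() == ""
        back = read_bundle(tmp_path)
        assert all(v == [] for v in back.peaks[tissue].values())
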