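"""Splice-form labels, Z transform, phase calls and delta events."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from promsplice import splicing
from promsplice.occupancy import OccupancyProfile
from promsplice.splicing import (
    PsiTable,
    assign_phase,
    build_delta_events,
    filter_genes,
    label_splice_form,
    z_psi_table,
    z_transform,
)


class TestLabelSpliceForm:
    @pytest.mark.parametrize(
        "psi,expected",
        [
            (0.1, "exclusion"),
            (0.9, "inclusion"),
            (0.2, "intermediate"),
            (0.8, "intermediate"),
            (0.5, "intermediate"),
        ],
    )
    def test_thresholds(self, psi, expected):
        assert label_splice_form(psi) == expected

    def test_missing_gets_no_label(self):
        assert label_splice_form(float("nan")) is None


class TestFilterGenes:
    def test_examples(self):
        psi = pd.DataFrame(
            {
                "t1": [0.1, 0.50, 0.1, np.nan],
                "t2": [0.9, 0.65, 0.9, 0.2],
                "t3": [0.5, 0.60, np.nan, 0.9],
            },
            index=["kept", "small_range", "two_tissues", "also_two"],
        )
        assert filter_genes(PsiTable(psi)) == ["kept"]


class TestZTransform:
    def test_mean_zero_sd_one(self):
        z = z_transform(np.array([0.1, 0.35, 0.6, 0.9]))
        assert np.mean(z) == pytest.approx(0.0, abs=1e-12)
        assert np.std(z) == pytest.approx(1.0, abs=1e-12)

    def test_two_point_population_sd(self):
        # mean 0.5, population sd 0.4 -> z = (-1, +1)
        z = z_transform(np.array([0.1, 0.9]))
        assert z == pytest.approx([-1.0, 1.0], abs=1e-12)

    def test_missing_entries_preserved(self):
        row = pd.Series([0.1, np.nan, 0.9], index=list("abc"))
        z = z_transform(row)
        assert np.isnan(z["b"])
        assert np.nanmean(z) == pytest.approx(0.0, abs=1e-12)

    def test_constant_row_rejected(self):
        with pytest.raises(ValueError):
            z_transform(np.array([0.5, 0.5, 0.5]))


class TestAssignPhase:
    def test_ten_distinct_values(self):
        z = pd.Series(np.linspace(-2, 2, 10), index=[f"t{i}" for i in range(10)])
        phases = assign_phase(z)
        assert (phases == "low").sum() == 2
        assert (phases == "high").sum() == 2
        assert set(z[phases == "low"].index) == {"t0", "t1"}
        assert set(z[phases == "high"].index) == {"t8", "t9"}

    def test_five_values_one_per_tail(self):
        z = pd.Series([0.3, -1.0, 0.1, 2.0, -0.2])
        phases = assign_phase(z)
        assert (phases == "low").sum() == 1
        assert (phases == "high").sum() == 1

    @pytest.mark.parametrize("n", [3, 4, 6, 7, 9, 12])
    def test_tail_sizes_match_rank_oracle(self, n):
        rng = np.random.default_rng(n)
        z = pd.Series(rng.normal(size=n))
        phases = assign_phase(z)
        k = max(int(np.floor(0.2 * n)), 1)
        order = np.argsort(z.values, kind="stable")
        assert set(np.nonzero((phases == "low").values)[0]) == set(order[:k])
        assert set(np.nonzero((phases == "high").values)[0]) == set(order[n - k:])

    def test_requires_three_values(self):
        with pytest.raises(ValueError):
            assign_phase(pd.Series([0.1, 0.2]))


def _profile(gene, tissue, vector, sites=None):
    n_tf = len(vector)
    mat = sparse.lil_matrix((2500, n_tf), dtype=np.int8)
    for tf_idx in np.nonzero(vector)[0]:
        start = 100 + 60 * int(tf_idx)
        mat[start : start + 8, tf_idx] = 1
    return OccupancyProfile(
        gene_id=gene, tissue=tissue, tf_order=tuple(f"TF{i}" for i in range(n_tf)),
        vector=np.asarray(vector, dtype=np.int8), positional=mat.tocsr(),
    )


def _zpsi(genes, tissues, z, phase):
    zdf = pd.DataFrame(z, index=genes, columns=tissues)
    pdf = pd.DataFrame(phase, index=genes, columns=tissues)
    return splicing.ZPsiTable(z=zdf, phase=pdf)


class TestDeltaEvents:
    def _setup(self):
        tissues = ["t1", "t2", "t3", "t4"]
        vectors = {
            "t1": [1, 0, 1],
            "t2": [1, 1, 0],
            "t3": [1, 0, 1],
            "t4": [0, 0, 1],
        }
        profiles = {("g", t): _profile("g", t, v) for t, v in vectors.items()}
        zpsi = _zpsi(
            ["g"], tissues,
            [[-1.5, -0.5, 0.5, 1.5]],
            [["low", "middle", "middle", "high"]],
        )
        return profiles, zpsi

    def test_middle_phases_excluded_and_labels(self):
        profiles, zpsi = self._setup()
        events = build_delta_events(profiles, zpsi)
        assert len(events) == 1  # only (t1, t4): the two non-middle tissues
        e = events[0]
        assert e.label == "discordance"
        assert e.delta_z == pytest.approx(3.0)
        assert list(e.delta_vector) == [1, 0, 0]

    def test_identical_vectors_give_zero_delta(self):
        profiles, zpsi = self._setup()
        zpsi.phase.loc["g"] = ["low", "middle", "high", "middle"]
        events = build_delta_events(profiles, zpsi)
        assert len(events) == 1
        assert events[0].label == "discordance"
        assert not events[0].delta_vector.any()
        assert events[0].delta_positional().nnz == 0

    def test_event_count_is_pairs_of_phased_tissues(self):
        tissues = [f"t{i}" for i in range(8)]
        rng = np.random.default_rng(0)
        profiles = {
            ("g", t): _profile("g", t, rng.integers(0, 2, 4)) for t in tissues
        }
        for h, l in [(2, 3), (1, 1), (3, 2)]:
            phases = ["high"] * h + ["low"] * l + ["middle"] * (8 - h - l)
            zpsi = _zpsi(["g"], tissues, [np.linspace(-1, 1, 8)], [phases])
            events = build_delta_events(profiles, zpsi)
            expected = len(list(itertools.combinations(range(h + l), 2)))
            assert len(events) == expected

    def test_delta_fields_symmetric_in_tissue_order(self):
        profiles, zpsi = self._setup()
        ev = build_delta_events(profiles, zpsi)[0]
        swapped_z = zpsi.z[["t4", "t3", "t2", "t1"]]
        swapped_p = zpsi.phase[["t4", "t3", "t2", "t1"]]
        ev2 = build_delta_events(
            profiles, splicing.ZPsiTable(z=swapped_z, phase=swapped_p)
        )[0]
        assert ev.label == ev2.label
        assert ev.delta_z == pytest.approx(ev2.delta_z)
        assert np.array_equal(ev.delta_vector, ev2.delta_vector)
        assert (ev.delta_positional() != ev2.delta_positional()).nnz == 0

    def test_no_event_is_both_labels(self):
        profiles, zpsi = self._setup()
        events = build_delta_events(profiles, zpsi)
        keys = [(e.gene_id, frozenset((e.tissue_a, e.tissue_b))) for e in events]
        assert len(keys) == len(set(keys))


class TestZPsiTable:
    def test_full_table_filters_transforms_and_phases(self):
        rng = np.random.default_rng(3)
        psi = pd.DataFrame(
            rng.uniform(0, 1, (20, 6)),
            index=[f"g{i}" for i in range(20)],
            columns=[f"t{j}" for j in range(6)],
        )
        table = z_psi_table(PsiTable(psi))
        for g in table.z.index:
            z = table.z.loc[g].dropna()
            assert z.mean() == pytest.approx(0.0, abs=1e-9)
            assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-9)
            phases = table.phase.loc[g].dropna()
            assert (phases == "low").sum() >= 1
            assert (phases == "high").sum() >= 1


def test_psi_roundtrip(tmp_path):
    psi = pd.DataFrame(
        [[0.1, np.nan, 0.9], [0.4, 0.5, 0.6]],
        index=["g1", "g2"], columns=["t1", "t2", "t3"],
    )
    path = tmp_path / "psi.tsv"
    splicing.write_psi(PsiTable(psi), path)
    back = splicing.read_psi(path)
    pd.testing.assert_frame_equal(back.psi, psi, atol=1e-6)
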