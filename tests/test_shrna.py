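"""shRNA silencing scores: probe ratios, gene collapse, group statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import driverlens as dl
from driverlens.errors import ValidationError


def make_screen(rows, conditions, probe_to_gene, groups, reference="DNA"):
    scores = pd.DataFrame(rows, index=list(probe_to_gene), columns=conditions)
    return dl.ShrnaScreen(
        scores=scores, probe_to_gene=probe_to_gene, groups=groups, reference_group=reference
    )


def simple_screen(values_by_probe):
    """One cell line with two replicates, pool with two replicates."""
    probes = list(values_by_probe)
    return make_screen(
        [values_by_probe[p] for p in probes],
        ["h_r1", "h_r2", "DNA_r1", "DNA_r2"],
        {p: "G1" for p in probes},
        {"h": ["h_r1", "h_r2"], "DNA": ["DNA_r1", "DNA_r2"]},
    )


class TestProbeRatio:
    def test_fourfold_enrichment(self):
        screen = simple_screen({"p1": [8.0, 8.0, 2.0, 2.0]})
        assert dl.probe_log2ratio(screen, "h", "p1") == pytest.approx(2.0)

    def test_equal_means_give_zero(self):
        screen = simple_screen({"p1": [3.0, 5.0, 4.0, 4.0]})
        assert dl.probe_log2ratio(screen, "h", "p1") == pytest.approx(0.0)

    def test_ratio_of_replicate_means(self):
        # cell-line replicates {1,2,4}, pool {2}: log2((7/3)/2)
        screen = make_screen(
            [[1.0, 2.0, 4.0, 2.0]],
            ["h_r1", "h_r2", "h_r3", "DNA_r1"],
            {"p1": "G1"},
            {"h": ["h_r1", "h_r2", "h_r3"], "DNA": ["DNA_r1"]},
        )
        assert dl.probe_log2ratio(screen, "h", "p1") == pytest.approx(math.log2(7 / 6))

    def test_non_positive_mean_is_missing(self):
        screen = simple_screen({"p1": [-4.0, 2.0, 2.0, 2.0]})
        assert dl.probe_log2ratio(screen, "h", "p1") is None

    def test_unknown_probe_is_error(self):
        screen = simple_screen({"p1": [1, 1, 1, 1]})
        with pytest.raises(ValidationError):
            dl.probe_log2ratio(screen, "h", "zz")

    @settings(max_examples=40, derandomize=True)
    @given(
        reps=st.lists(st.floats(0.1, 50), min_size=1, max_size=4),
        pool=st.lists(st.floats(0.1, 50), min_size=1, max_size=4),
        c=st.floats(0.01, 100),
    )
    def test_scale_invariance_and_shift(self, reps, pool, c):
        """Scaling both groups by c is a no-op; scaling only the cell line
        shifts the ratio by exactly log2(c)."""
        conditions = [f"h_r{i}" for i in range(len(reps))] + [
            f"DNA_r{i}" for i in range(len(pool))
        ]
        groups = {
            "h": conditions[: len(reps)],
            "DNA": conditions[len(reps):],
        }
        base = make_screen([reps + pool], conditions, {"p": "G"}, groups)
        both = make_screen(
            [[v * c for v in reps + pool]], conditions, {"p": "G"}, groups
        )
        line_only = make_screen(
            [[v * c for v in reps] + pool], conditions, {"p": "G"}, groups
        )
        r0 = dl.probe_log2ratio(base, "h", "p")
        assert dl.probe_log2ratio(both, "h", "p") == pytest.approx(r0, abs=1e-12)
        assert dl.probe_log2ratio(line_only, "h", "p") - r0 == pytest.approx(
            math.log2(c), abs=1e-9
        )


class TestGeneEffect:
    def _multi_probe_screen(self, ratios):
        # construct pool=1 so each probe's ratio is log2 of its cell-line mean
        probes = {f"p{i}": [2.0**r, 2.0**r, 1.0, 1.0] for i, r in enumerate(ratios)}
        return simple_screen(probes)

    def test_top_scoring_probe_wins(self):
        screen = self._multi_probe_screen([-1.0, 0.5, 2.0])
        eff = dl.gene_effect(screen, "h", "G1")
        assert eff.log2ratio == pytest.approx(2.0) and eff.n_probes == 3

    def test_single_probe_identity(self):
        screen = self._multi_probe_screen([0.7])
        assert dl.gene_effect(screen, "h", "G1").log2ratio == pytest.approx(0.7)

    def test_ties_are_well_defined(self):
        screen = self._multi_probe_screen([1.0, 1.0])
        assert dl.gene_effect(screen, "h", "G1").log2ratio == pytest.approx(1.0)

    def test_direction_min(self):
        screen = self._multi_probe_screen([-1.0, 2.0])
        assert dl.gene_effect(screen, "h", "G1", direction="min").log2ratio == pytest.approx(-1.0)

    def test_all_probes_missing_gives_missing_effect(self):
        screen = simple_screen({"p1": [-1.0, -1.0, 1.0, 1.0]})
        assert dl.gene_effect(screen, "h", "G1").log2ratio is None

    def test_max_dominates_every_probe(self):
        ratios = [-0.5, 0.25, 1.5, 0.9]
        screen = self._multi_probe_screen(ratios)
        eff = dl.gene_effect(screen, "h", "G1")
        for i in range(len(ratios)):
            assert eff.log2ratio >= dl.probe_log2ratio(screen, "h", f"p{i}") - 1e-12


class TestProliferationCount:
    def _three_line_screen(self, per_line):
        conditions = [f"CL{i}_r0" for i in range(3)] + ["DNA_r0"]
        groups = {f"CL{i}": [f"CL{i}_r0"] for i in range(3)}
        groups["DNA"] = ["DNA_r0"]
        return make_screen(
            [[2.0**v if v is not None else -1.0 for v in per_line] + [1.0]],
            conditions,
            {"p1": "G1"},
            groups,
        )

    def test_count_above_zero(self):
        screen = self._three_line_screen([1.0, -1.0, 0.2])
        res = dl.proliferation_count(screen, "G1", ["CL0", "CL1", "CL2"])
        assert res["n_increased"] == 2 and res["missing_lines"] == []

    def test_all_missing(self):
        screen = self._three_line_screen([None, None, None])
        res = dl.proliferation_count(screen, "G1", ["CL0", "CL1", "CL2"])
        assert res["n_increased"] == 0 and len(res["missing_lines"]) == 3

    def test_infinite_threshold(self):
        screen = self._three_line_screen([1.0, 2.0, 3.0])
        res = dl.proliferation_count(screen, "G1", ["CL0", "CL1", "CL2"],
                                     threshold=math.inf)
        assert res["n_increased"] == 0


class TestGroupComparison:
    def test_identical_groups(self):
        res = dl.compare_silencing_groups([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert res["wilcoxon_p"] == pytest.approx(1.0)

    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(1, 0.3, 20), rng.normal(0, 0.3, 20)
        ab = dl.compare_silencing_groups(a, b)
        ba = dl.compare_silencing_groups(b, a)
        assert ab["wilcoxon_p"] == pytest.approx(ba["wilcoxon_p"])

    def test_planted_shift_is_detected(self):
        rng = np.random.default_rng(11)
        supp = rng.normal(1.0, 0.3, 50)
        background = rng.normal(0.0, 0.3, 50)
        res = dl.compare_silencing_groups(supp, background)
        assert res["wilcoxon_p"] < 0.01
        assert res["median_a"] > res["median_b"]

    def test_undersized_group_is_error(self):
        with pytest.raises(ValidationError):
            dl.compare_silencing_groups([1.0, 2.0], [1.0, 2.0, 3.0])


def test_gct_groups_round_trip(tmp_path):
    """GCT + group map written to disk reproduce the gene effects."""
    screen = simple_screen({"p1": [8.0, 8.0, 2.0, 2.0], "p2": [1.0, 1.0, 2.0, 2.0]})
    dl.write_gct(screen, tmp_path / "s.gct")
    cond_map = {c: g for g, conds in screen.groups.items() for c in conds}
    dl.io.write_group_map(cond_map, tmp_path / "groups.tsv")
    back = dl.read_gct(tmp_path / "s.gct")
    back = dl.assign_groups(back, dl.read_group_map(tmp_path / "groups.tsv"), "DNA")
    assert dl.gene_effect(back, "h", "G1").log2ratio == pytest.approx(2.0)
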