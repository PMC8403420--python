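"""Statistics (Mann–Whitney, Welch, BH, KW+Dunn) and DMG calling."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylodyn import (
    BetaMatrix,
    SampleRecord,
    SampleSheet,
    benjamini_hochberg,
    call_dmgs,
    compare_stages,
    gene_beta,
    two_group_test,
    validate_dmgs,
)
from methylodyn.data_io import ProbeAnnotation
from methylodyn.dmg_analysis import AnalysisError
from methylodyn.synthetic_cohort import generate_dmg_benchmark


def _annotation(pairs, region="TSS200"):
    rows = [(p, g, region, "chr1") for p, g in pairs]
    return ProbeAnnotation(pd.DataFrame(
        rows, columns=["probe_id", "gene", "region", "chromosome"]))


class TestGeneBeta:
    def test_mean_over_regulatory_probes(self):
        frame = pd.DataFrame({"s1": [0.2, 0.4], "s2": [0.6, np.nan]},
                             index=["cg1", "cg2"])
        ann = _annotation([("cg1", "G1"), ("cg2", "G1")])
        gb = gene_beta(frame, ann)
        assert gb.loc["G1", "s1"] == pytest.approx(0.3)
        assert gb.loc["G1", "s2"] == pytest.approx(0.6)  # missing skipped

    def test_body_probes_excluded(self):
        frame = pd.DataFrame({"s1": [0.2, 0.9]}, index=["cg1", "cg2"])
        rows = [("cg1", "G1", "TSS200", "chr1"), ("cg2", "G1", "BODY", "chr1")]
        ann = ProbeAnnotation(pd.DataFrame(
            rows, columns=["probe_id", "gene", "region", "chromosome"]))
        assert gene_beta(frame, ann).loc["G1", "s1"] == pytest.approx(0.2)

    def test_unknown_gene_error(self):
        frame = pd.DataFrame({"s1": [0.2]}, index=["cg1"])
        ann = _annotation([("cg1", "G1")])
        with pytest.raises(AnalysisError, match="G9"):
            gene_beta(frame, ann, ["G9"])

    def test_matches_brute_force(self, rng):
        probes = [f"cg{i:02d}" for i in range(24)]
        frame = pd.DataFrame(rng.random((24, 6)), index=probes)
        pairs = [(p, f"G{i % 5}") for i, p in enumerate(probes)]
        gb = gene_beta(frame, _annotation(pairs))
        gene_of = dict(pairs)
        for gene in gb.index:
            member = [p for p in probes if gene_of[p] == gene]
            expected = frame.loc[member].mean(axis=0)
            assert np.allclose(gb.loc[gene], expected)


class TestTwoGroupTest:
    def test_mann_whitney_exact_worked_case(self):
        res = two_group_test([1, 2, 3], [4, 5, 6], method="mann_whitney")
        assert res.test_name == "MANN_WHITNEY"
        assert res.statistic == 0.0
        assert res.p == pytest.approx(0.1)

    def test_identical_values_p_one(self):
        res = two_group_test([0.5] * 4, [0.5] * 4, method="mann_whitney")
        assert res.p == 1.0

    def test_group_too_small(self):
        with pytest.raises(AnalysisError):
            two_group_test([1.0], [2.0, 3.0])

    def test_exact_equals_enumeration_for_all_small_sizes(self, rng):
        """Exact MW two-sided p equals full enumeration, n1+n2 ≤ 12."""
        for n1 in range(2, 7):
            for n2 in range(n1, 13 - n1):
                pooled = rng.normal(size=n1 + n2)
                while len(np.unique(pooled)) < len(pooled):
                    pooled = rng.normal(size=n1 + n2)
                x, y = pooled[:n1], pooled[n1:]
                res = two_group_test(x, y, method="mann_whitney")
                u_obs = sum(xi > yj for xi in x for yj in y)
                center = n1 * n2 / 2
                count = total = 0
                for idx in itertools.combinations(range(n1 + n2), n1):
                    xs = pooled[list(idx)]
                    ys = np.delete(pooled, list(idx))
                    u = sum(xi > yj for xi in xs for yj in ys)
                    total += 1
                    if abs(u - center) >= abs(u_obs - center) - 1e-12:
                        count += 1
                assert res.p == pytest.approx(count / total, abs=1e-12), \
                    (n1, n2)

    def test_welch_consistent_with_permutation_floor(self):
        x, y = (0.1, 0.2, 0.3), (0.6, 0.7, 0.8)
        res = two_group_test(x, y, method="welch_t")
        pooled = np.array(x + y)
        t_obs = abs(res.statistic)
        count = total = 0
        from scipy import stats
        for idx in itertools.combinations(range(6), 3):
            xs = pooled[list(idx)]
            ys = np.delete(pooled, list(idx))
            t = abs(stats.ttest_ind(xs, ys, equal_var=False).statistic)
            total += 1
            if t >= t_obs - 1e-9:
                count += 1
        perm_p = count / total  # oracle resolution: 2/20
        assert perm_p == pytest.approx(0.1)
        assert res.p <= perm_p  # agreement within the oracle's resolution

    def test_auto_uses_rank_test_for_smallest_groups(self):
        res = two_group_test([0.1, 0.2, 0.3], [0.6, 0.7, 0.8], method="auto")
        assert res.test_name == "MANN_WHITNEY"


class TestBenjaminiHochberg:
    def test_hand_step_up_vectors(self):
        assert np.allclose(benjamini_hochberg([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])
        assert np.allclose(benjamini_hochberg([0.005, 0.04, 0.04, 0.8]),
                           [0.02, 0.05333333333333334, 0.05333333333333334, 0.8])
        assert benjamini_hochberg([0.3])[0] == pytest.approx(0.3)
        assert np.allclose(benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(AnalysisError):
            benjamini_hochberg([0.5, 1.5])

    def test_against_statsmodels_oracle(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.random(int(rng.integers(1, 40)))
            _, q_sm, _, _ = multipletests(p, method="fdr_bh")
            assert np.allclose(benjamini_hochberg(p), q_sm, atol=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0, width=32),
                    min_size=1, max_size=25))
    def test_properties(self, pvals):
        q = benjamini_hochberg(pvals)
        p = np.asarray(pvals)
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()
        # permutation invariance (up to matching reorder)
        perm = np.random.RandomState(0).permutation(len(pvals))
        q_perm = benjamini_hochberg(p[perm])
        assert np.allclose(q_perm, q[perm])


def _two_subject_cohort():
    """Two discovery subjects; gene GA differential in both, GB in one."""
    rng = np.random.default_rng(77)
    probes = [f"cg{i:02d}" for i in range(6)]
    pairs = [("cg00", "GA"), ("cg01", "GA"), ("cg02", "GB"), ("cg03", "GB"),
             ("cg04", "GC"), ("cg05", "GC")]
    records, labels = [], {}
    cols = {}
    for subject in ("P1", "P2"):
        for j in range(3):
            sid = f"{subject}_T{j}"
            records.append(SampleRecord(sid, subject,
                                        "BL" if j == 0 else f"FU{j}", 4.0 * j))
            labels[sid] = "PC_SUBSTANTIAL"
            ga = 0.75
            gb = 0.75 if subject == "P1" else 0.30
            cols[sid] = [ga, ga, gb, gb, 0.5, 0.5]
    for k in range(12):
        subject = f"N{k % 4 + 1}"
        tp = k // 4
        sid = f"{subject}_T{tp}"
        records.append(SampleRecord(sid, subject,
                                    "BL" if tp == 0 else f"FU{tp}", 4.0 * tp))
        labels[sid] = "NPC"
        cols[sid] = [0.30, 0.30, 0.30, 0.30, 0.5, 0.5]
    records.sort(key=lambda r: (r.subject_id, r.month))
    noise = rng.normal(0, 0.01, size=(6, len(cols)))
    frame = pd.DataFrame(
        {sid: np.clip(np.array(cols[sid]) + noise[:, i], 0, 1)
         for i, sid in enumerate(sorted(cols))}, index=probes)
    sheet = SampleSheet(records)
    return BetaMatrix(frame), _annotation(pairs), sheet, labels


class TestCallDMGs:
    def test_planted_calls_directions_and_uniqueness(self):
        beta, ann, sheet, labels = _two_subject_cohort()
        table = call_dmgs(beta, ann, sheet, labels,
                          candidate_genes=["GA", "GB", "GC"])
        called = table.called()
        # GA hyper in both subjects, GB hyper only in P1, GC never
        assert set(table.per_subject["P1"]) == {"GA", "GB"}
        assert set(table.per_subject["P2"]) == {"GA"}
        assert (called["direction"] == "HYPER").all()
        assert table.summary["n_hyper"] == 2
        # GB unique to one subject of the two hyper genes → 0.5
        assert table.summary["unique_fraction_hyper"] == pytest.approx(0.5)
        # direction always matches the sign of the PC−NPC contrast
        assert ((called["delta_beta"] > 0)
                == (called["direction"] == "HYPER")).all()

    def test_single_pc_subject_excluded(self):
        beta, ann, sheet, labels = _two_subject_cohort()
        labels = dict(labels)
        labels["P2_T1"] = "NPC"
        labels["P2_T2"] = "NPC"  # P2 left with one PC sample
        table = call_dmgs(beta, ann, sheet, labels,
                          candidate_genes=["GA", "GB", "GC"])
        assert "P2" not in table.per_subject
        assert table.summary["excluded_subjects"] == ["P2"]

    def test_no_eligible_subject_error(self):
        beta, ann, sheet, labels = _two_subject_cohort()
        labels = {k: "NPC" for k in labels}
        with pytest.raises(AnalysisError):
            call_dmgs(beta, ann, sheet, labels, candidate_genes=["GA"])

    def test_planted_benchmark_recall_single_seed(self):
        b = generate_dmg_benchmark(seed=41, n_genes=300, n_hyper=20,
                                   n_hypo=20)
        table = call_dmgs(b.beta, b.annotation, b.sheet, b.labels,
                          candidate_genes=sorted(set(b.plan["gene"])))
        plan = b.plan.drop_duplicates("gene").set_index("gene")["direction"]
        called = table.called()
        for d in ("HYPER", "HYPO"):
            planted = set(plan[plan == d].index)
            got = set(called.loc[called["direction"] == d, "gene"])
            assert len(got & planted) / len(planted) >= 0.9


class TestValidateDMGs:
    def test_external_list_overlap_fraction(self):
        b = generate_dmg_benchmark(seed=42, n_genes=200, n_hyper=10, n_hypo=10)
        table = call_dmgs(b.beta, b.annotation, b.sheet, b.labels,
                          candidate_genes=sorted(set(b.plan["gene"])))
        v = generate_dmg_benchmark(seed=42, plan=b.plan, noise_seed=7)
        validated = validate_dmgs(table, v.beta, v.annotation, v.labels)
        genes = sorted(validated.records.loc[validated.records["validated"],
                                             "gene"])
        half = genes[: len(genes) // 2]
        rep = validate_dmgs(table, v.beta, v.annotation, v.labels,
                            external_gene_lists={"HALF": half})
        assert rep.external_overlap["HALF"] == pytest.approx(
            len(half) / len(genes))

    def test_disjoint_cohorts_reported_empty(self, caplog):
        b = generate_dmg_benchmark(seed=43, n_genes=50, n_hyper=5, n_hypo=5)
        table = call_dmgs(b.beta, b.annotation, b.sheet, b.labels,
                          candidate_genes=sorted(set(b.plan["gene"])))
        other = generate_dmg_benchmark(seed=44, n_genes=30, n_hyper=2,
                                       n_hypo=2)
        renamed = other.annotation.table.copy()
        renamed["gene"] = "X_" + renamed["gene"]
        foreign = ProbeAnnotation(renamed)
        rep = validate_dmgs(table, other.beta, foreign, other.labels)
        assert rep.n_tested == 0 and rep.validated_fraction is None


class TestCompareStages:
    def _gene_frame(self, groups):
        vals = [v for g in groups for v in g]
        cols = [f"s{i}" for i in range(len(vals))]
        labels = {f"s{i}": f"G{gi}"
                  for i, gi in enumerate(
                      gi for gi, g in enumerate(groups) for _ in g)}
        return pd.DataFrame([vals], index=["gene1"], columns=cols), labels

    def test_identical_groups_zero_statistic(self):
        frame, labels = self._gene_frame([[2, 2], [2, 2], [2, 2]])
        res = compare_stages(frame, labels)
        assert res.kruskal.iloc[0]["statistic"] == 0.0
        assert res.kruskal.iloc[0]["p"] == 1.0
        assert (res.dunn["p"] == 1.0).all()

    def test_permutation_p_matches_enumeration(self):
        from scipy.stats import rankdata

        groups = [[1, 2], [3, 4], [5, 6]]
        frame, labels = self._gene_frame(groups)
        res = compare_stages(frame, labels, method="permutation")

        def kw_h(gs):
            pooled = np.concatenate(gs)
            ranks = rankdata(pooled)
            n = len(pooled)
            h, i = 0.0, 0
            for g in gs:
                r = ranks[i:i + len(g)]
                h += r.sum() ** 2 / len(g)
                i += len(g)
            return 12 / (n * (n + 1)) * h - 3 * (n + 1)

        pooled = [1, 2, 3, 4, 5, 6]
        h_obs = kw_h([np.array(g) for g in groups])
        count = total = 0
        for a in itertools.combinations(range(6), 2):
            rest1 = [i for i in range(6) if i not in a]
            for b in itertools.combinations(rest1, 2):
                c = [i for i in rest1 if i not in b]
                gs = [np.array([pooled[i] for i in idx]) for idx in (a, b, c)]
                total += 1
                if kw_h(gs) >= h_obs - 1e-12:
                    count += 1
        assert total == 90
        assert res.kruskal.iloc[0]["p"] == pytest.approx(count / total)
        # the asymptotic approximation should at least coarsely agree
        asym = compare_stages(frame, labels).kruskal.iloc[0]["p"]
        assert abs(asym - count / total) < 0.05

    def test_dunn_detects_extreme_group(self):
        frame, labels = self._gene_frame(
            [[0.1, 0.12, 0.11], [0.5, 0.52, 0.51], [0.9, 0.92, 0.91]])
        res = compare_stages(frame, labels)
        pair = res.dunn[(res.dunn["group_a"] == "G0")
                        & (res.dunn["group_b"] == "G2")]
        assert pair.iloc[0]["p"] < 0.05
        assert (res.dunn["q"] >= res.dunn["p"] - 1e-12).all()

    def test_two_groups_rejected(self):
        frame, labels = self._gene_frame([[1, 2], [3, 4]])
        with pytest.raises(AnalysisError, match="two_group_test"):
            compare_stages(frame, labels)
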