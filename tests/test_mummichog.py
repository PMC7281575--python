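import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metaboflow import (
    MummichogParams,
    build_empirical_compounds,
    convert_library,
    enrich_mummichog,
    ion_forms,
    match_mz,
    simulate_pathway_data,
)
from metaboflow.mummichog import normalize_ion_name


class TestIonForms:
    def test_primary_set_covers_all_published_spellings(self):
        spellings = [
            "M+H[1+]", "M+Na[1+]", "M−H2O+H[1+]", "M−H[−]", "M−2H[2−]", "M−H2O−H[−]",
            "M+H [1+]", "M+Na [1+]", "M−H2O+H [1+]", "M−H [1−]", "M−2H [2−]", "M−H2O−H[1−]",
        ]
        primary = {f.name for f in ion_forms("positive") + ion_forms("negative") if f.is_primary}
        for s in spellings:
            assert normalize_ion_name(s) in primary

    def test_whitespace_variants_collapse(self):
        assert normalize_ion_name("M+H [1+]") == normalize_ion_name("M+H[1+]")
        assert normalize_ion_name("M−H [1−]") == normalize_ion_name("M-H[-]")

    def test_hexose_protonated_mass(self):
        m_plus_h = next(f for f in ion_forms("positive") if f.name == "M+H[1+]")
        assert m_plus_h.theoretical_mz(180.0634) == pytest.approx(181.0707, abs=2e-4)


class TestMatchMz:
    def test_exact_hexose_match(self):
        feats = pd.DataFrame({"mz": [181.0707], "rt": [100.0]})
        comps = pd.DataFrame({"id": ["hexose"], "mass": [180.0634]})
        out = match_mz(feats, comps, MummichogParams(ppm=5))
        assert any(c == "hexose" and f.name == "M+H[1+]" for _, c, f in out)

    def test_ten_ppm_off_does_not_match_at_five(self):
        feats = pd.DataFrame({"mz": [181.0707 * (1 + 10e-6)], "rt": [100.0]})
        comps = pd.DataFrame({"id": ["hexose"], "mass": [180.0634]})
        out = match_mz(feats, comps, MummichogParams(ppm=5))
        assert not any(f.name == "M+H[1+]" for _, _, f in out)

    def test_empty_compound_list(self):
        feats = pd.DataFrame({"mz": [181.07], "rt": [1.0]})
        assert match_mz(feats, pd.DataFrame({"id": [], "mass": []}), MummichogParams()) == []

    def test_matches_equal_exhaustive_triples(self):
        rng = np.random.default_rng(0)
        params = MummichogParams(ppm=8)
        comps = pd.DataFrame(
            {"id": [f"C{i}" for i in range(10)], "mass": rng.uniform(100, 500, 10)}
        )
        forms = ion_forms("positive")
        mzs = []
        for i in range(20):
            form = forms[i % len(forms)]
            mass = comps["mass"].iloc[i % 10]
            mzs.append(form.theoretical_mz(mass) * (1 + rng.uniform(-15e-6, 15e-6)))
        feats = pd.DataFrame({"mz": mzs, "rt": rng.uniform(0, 600, 20)})
        got = {(fi, cid, form.name) for fi, cid, form in match_mz(feats, comps, params)}
        expected = set()
        for fi, cid_mass, form in itertools.product(
            range(20), comps.itertuples(index=False), forms
        ):
            theo = form.theoretical_mz(cid_mass.mass)
            if abs(feats["mz"].iloc[fi] - theo) / theo <= params.ppm * 1e-6:
                expected.add((fi, cid_mass.id, form.name))
        assert got == expected


def brute_force_stages(matches, features, params):
    """Independent rule-by-rule EC construction for toy inputs."""
    rts = features["rt"].to_numpy()
    mzs = features["mz"].to_numpy()
    window = params.rt_tol if params.rt_tol is not None else rts.max() * params.rt_frac
    # stage 1: connected components of the RT-proximity graph per compound
    initial = []
    by_compound = {}
    for fi, cid, form in matches:
        by_compound.setdefault(cid, []).append((fi, form.name))
    for cid in sorted(by_compound):
        members = by_compound[cid]
        parent = list(range(len(members)))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                if abs(rts[members[a][0]] - rts[members[b][0]]) <= window:
                    parent[find(a)] = find(b)
        comp = {}
        for i in range(len(members)):
            comp.setdefault(find(i), []).append(members[i])
        for group in comp.values():
            initial.append(({cid}, sorted(set(group))))
    # stage 2: merge ECs sharing an (mz, form) member at the same RT, to fixpoint
    merged = [list(e) for e in initial]
    changed = True
    while changed:
        changed = False
        for a in range(len(merged)):
            for b in range(a + 1, len(merged)):
                share = False
                for fa, na in merged[a][1]:
                    for fb, nb in merged[b][1]:
                        if (
                            na == nb
                            and abs(mzs[fa] - mzs[fb]) <= mzs[fa] * params.ppm * 1e-6
                            and abs(rts[fa] - rts[fb]) <= window
                        ):
                            share = True
                if share:
                    merged[a] = [
                        merged[a][0] | merged[b][0],
                        sorted(set(merged[a][1]) | set(merged[b][1])),
                    ]
                    del merged[b]
                    changed = True
                    break
            if changed:
                break
    # stage 3: primary filter
    primary = {f.name for f in ion_forms(params.mode) if f.is_primary}
    final = [e for e in merged if any(n in primary for _, n in e[1])]
    return initial, merged, final


class TestEmpiricalCompounds:
    def _params(self, **kw):
        return MummichogParams(ppm=10, **kw)

    def test_distant_features_split_into_two_ecs(self):
        feats = pd.DataFrame({"mz": [181.0707, 181.0707], "rt": [100.0, 200.0]})
        comps = pd.DataFrame({"id": ["C1"], "mass": [180.0634]})
        params = self._params(rt_tol=12.0)
        stages = build_empirical_compounds(match_mz(feats, comps, params), feats, params)
        assert len(stages.initial) == 2

    def test_default_window_is_two_percent_of_max_rt(self):
        feats = pd.DataFrame({"mz": [181.0707], "rt": [600.0]})
        comps = pd.DataFrame({"id": ["C1"], "mass": [180.0634]})
        params = self._params()
        stages = build_empirical_compounds(match_mz(feats, comps, params), feats, params)
        assert stages.window == pytest.approx(12.0)

    def test_stage_containment_and_primary_invariant(self):
        feats, lib, comps, _ = simulate_pathway_data(seed=8)
        params = self._params()
        stages = build_empirical_compounds(match_mz(feats, comps, params), feats, params)
        assert len(stages.final) <= len(stages.merged) <= len(stages.initial)
        assert all(ec.has_primary for ec in stages.final)
        assert all(ec.rt_span[1] - ec.rt_span[0] <= stages.window + 1e-9 or len(ec.compound_ids) > 1
                   for ec in stages.initial)

    def test_stages_match_brute_force_on_toy(self):
        # 8 features / 3 compounds with shared and isolated ions
        rng = np.random.default_rng(4)
        comps = pd.DataFrame({"id": ["C1", "C2", "C3"], "mass": [180.0634, 181.0634, 250.1]})
        forms = {f.name: f for f in ion_forms("positive")}
        rows = [
            (forms["M+H[1+]"].theoretical_mz(180.0634), 100.0),
            (forms["M+Na[1+]"].theoretical_mz(180.0634), 104.0),
            (forms["M+H[1+]"].theoretical_mz(180.0634), 300.0),
            (forms["M+H[1+]"].theoretical_mz(181.0634), 100.0),
            (forms["M+K[1+]"].theoretical_mz(181.0634), 102.0),
            (forms["M+H[1+]"].theoretical_mz(250.1), 400.0),
            (forms["M+NH4[1+]"].theoretical_mz(250.1), 500.0),
            (forms["M+H[1+]"].theoretical_mz(250.1) * (1 + 2e-6), 401.0),
        ]
        feats = pd.DataFrame(rows, columns=["mz", "rt"])
        params = self._params(rt_tol=12.0)
        matches = match_mz(feats, comps, params)
        stages = build_empirical_compounds(matches, feats, params)
        b_init, b_merged, b_final = brute_force_stages(matches, feats, params)

        def as_sets(ecs):
            return sorted(
                (frozenset(ec.compound_ids), frozenset((m[0], normalize_ion_name(m[3])) for m in ec.members))
                for ec in ecs
            )

        def b_as_sets(entries):
            return sorted(
                (frozenset(cids), frozenset((fi, normalize_ion_name(n)) for fi, n in mem))
                for cids, mem in entries
            )

        assert as_sets(stages.initial) == b_as_sets(b_init)
        assert as_sets(stages.merged) == b_as_sets(b_merged)
        assert as_sets(stages.final) == b_as_sets(b_final)

    def test_missing_rt_errors(self):
        feats = pd.DataFrame({"mz": [181.0707], "rt": [np.nan]})
        comps = pd.DataFrame({"id": ["C1"], "mass": [180.0634]})
        params = self._params()
        with pytest.raises(ValueError, match="retention time"):
            build_empirical_compounds(match_mz(feats, comps, params), feats, params)


class TestConvertLibrary:
    def test_set_algebra(self):
        feats, lib, comps, _ = simulate_pathway_data(seed=6)
        params = MummichogParams()
        stages = build_empirical_compounds(match_mz(feats, comps, params), feats, params)
        ec_lib = convert_library(lib, stages.final)
        for pw, ecs in ec_lib.items():
            assert ecs  # empty pathways dropped
            for ec in stages.final:
                should = bool(ec.compound_ids & lib[pw])
                assert (ec.ec_id in ecs) == should


class TestEnrichment:
    def test_ease_p_matches_hand_hypergeometric(self):
        # library where one pathway is exactly the significant EC set
        feats, lib, comps, _ = simulate_pathway_data(seed=12, sig_fraction=0.2)
        params = MummichogParams(n_perm=10, seed=0)
        stages = build_empirical_compounds(match_mz(feats, comps, params), feats, params)
        sig_idx = set(np.flatnonzero(feats["p"].to_numpy() <= params.p_cutoff))
        sig_ecs = [ec for ec in stages.final if ec.feature_indices & sig_idx]
        target_comps = set().union(*(ec.compound_ids for ec in sig_ecs[:5]))
        toy_lib = {"target": target_comps, "other": set(comps["id"][:20])}
        rows = enrich_mummichog(feats, toy_lib, comps, params)
        row = next(r for r in rows if r.pathway == "target")
        Q = len(stages.final)
        q = len(sig_ecs)
        expected = stats.hypergeom.sf(row.hits_sig - 2, Q, row.total_ecs, q)
        assert row.p_raw == pytest.approx(expected, rel=1e-9)

    def test_planted_pathway_recovered_first(self):
        feats, lib, comps, truth = simulate_pathway_data(effect=1.0, seed=5)
        rows = enrich_mummichog(feats, lib, comps, MummichogParams(n_perm=100, seed=1))
        assert rows[0].pathway == truth["enriched_pathway"]
        assert rows[0].p_gamma < 0.05

    def test_row_order_invariance_of_p_raw(self):
        feats, lib, comps, _ = simulate_pathway_data(effect=0.5, seed=9)
        params = MummichogParams(n_perm=20, seed=3)
        a = {r.pathway: r.p_raw for r in enrich_mummichog(feats, lib, comps, params)}
        shuffled = feats.sample(frac=1.0, random_state=0).reset_index(drop=True)
        b = {r.pathway: r.p_raw for r in enrich_mummichog(shuffled, lib, comps, params)}
        assert a == b

    def test_no_significant_features_errors(self):
        feats, lib, comps, _ = simulate_pathway_data(seed=2)
        feats["p"] = 0.9
        with pytest.raises(ValueError, match="no significant"):
            enrich_mummichog(feats, lib, comps, MummichogParams())

    def test_all_significant_errors(self):
        feats, lib, comps, _ = simulate_pathway_data(seed=2)
        feats["p"] = 1e-9
        with pytest.raises(ValueError, match="degenerate"):
            enrich_mummichog(feats, lib, comps, MummichogParams())
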