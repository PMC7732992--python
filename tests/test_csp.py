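import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from serpinmr import (
    combined_csp,
    csp_table,
    detect_doubled_peaks,
    flag_local_sites,
    generate_scenario,
    render_peaklists,
)
from serpinmr.peaklist_io import MethylPeak, MethylSite, PeakList

finite_ppm = st.floats(-1.0, 1.0, allow_nan=False)


class TestCombinedCSP:
    @pytest.mark.parametrize(
        "dH,dC,expected",
        [
            (0.0, 0.0, 0.0),
            (0.1, 0.0, 0.1),
            (0.0, 0.4, 0.1),
            (0.03, 0.10, 0.03905124837953327),  # sqrt(9e-4 + 6.25e-4)
        ],
    )
    def test_values(self, dH, dC, expected):
        assert combined_csp(dH, dC) == pytest.approx(expected, rel=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            combined_csp(float("nan"), 0.1)

    @given(dH=finite_ppm, dC=finite_ppm)
    @settings(max_examples=100, derandomize=True)
    def test_sign_symmetry(self, dH, dC):
        v = combined_csp(dH, dC)
        assert combined_csp(-dH, dC) == v
        assert combined_csp(dH, -dC) == v

    @given(dH=finite_ppm, dC=finite_ppm, scale=st.floats(1.0, 5.0))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_magnitudes(self, dH, dC, scale):
        assert combined_csp(scale * dH, dC) >= combined_csp(dH, dC) - 1e-15
        assert combined_csp(dH, scale * dC) >= combined_csp(dH, dC) - 1e-15


def _mini_list(label, entries, **kw):
    peaks = [
        MethylPeak(delta_H=h, delta_C=c, intensity=i, site=MethylSite.from_label(s))
        for s, h, c, i in entries
    ]
    return PeakList(state_label=label, peaks=peaks, **kw)


class TestCSPTable:
    def test_identical_lists_all_zero(self, peaklists):
        recs, untraced = csp_table(peaklists["M"], peaklists["M"])
        assert untraced == []
        assert all(r.dCH == 0 for r in recs)
        assert all(r.intensity_ratio == pytest.approx(1.0) for r in recs)

    def test_antisymmetry(self, peaklists):
        ab, _ = csp_table(peaklists["M"], peaklists["Z"])
        ba, _ = csp_table(peaklists["Z"], peaklists["M"])
        for r1, r2 in zip(ab, ba):
            assert r1.site == r2.site
            assert r1.dH == pytest.approx(-r2.dH)
            assert r1.dC == pytest.approx(-r2.dC)

    def test_untraced_site_reported(self):
        l1 = _mini_list("a", [("I10d1", 0.5, 12.0, 1), ("L20d1", 0.8, 24.0, 1),
                              ("A30b", 1.2, 18.0, 1)])
        l2 = _mini_list("b", [("I10d1", 0.5, 12.0, 1), ("L20d1", 0.8, 24.0, 1)])
        recs, untraced = csp_table(l1, l2)
        assert [s.label for s in untraced] == ["A30b"]
        assert {r.site.label for r in recs} == {"I10d1", "L20d1"}

    def test_no_shared_sites_errors(self):
        l1 = _mini_list("a", [("I10d1", 0.5, 12.0, 1)])
        l2 = _mini_list("b", [("L20d1", 0.8, 24.0, 1)])
        with pytest.raises(ValueError, match="no shared"):
            csp_table(l1, l2)

    def test_matches_generator_offsets_exactly(self):
        sc = generate_scenario(n_sites=40, seed=5, n_local_sites=0)
        lists = render_peaklists(sc, with_noise=False)
        recs, _ = csp_table(lists["M"], lists["M+716"])
        p_M = sc.p_I_per_variant["M"]
        by_site = {r.site: r for r in recs}
        for i, site in enumerate(sc.sites):
            expected = (1.0 - p_M) * (sc.delta_I[i] - sc.delta_N[i])
            assert by_site[site].dH == pytest.approx(expected[0], abs=1e-12)
            assert by_site[site].dC == pytest.approx(expected[1], abs=1e-12)

    def test_intensity_normalisation(self):
        l1 = _mini_list(
            "a", [("I10d1", 0.5, 12.0, 2.0), ("L20d1", 0.8, 24.0, 2.0)],
            concentration_uM=400, n_scans_norm=2,
        )
        l2 = _mini_list(
            "b", [("I10d1", 0.5, 12.0, 1.0), ("L20d1", 0.8, 24.0, 4.0)],
            concentration_uM=200, n_scans_norm=1,
        )
        recs, _ = csp_table(l1, l2)
        # (1/200)/(2/800) = 2 ; (4/200)/(2/800) = 8
        by = {r.site.label: r.intensity_ratio for r in recs}
        assert by["I10d1"] == pytest.approx(2.0)
        assert by["L20d1"] == pytest.approx(8.0)


class TestFlagLocalSites:
    def test_excluded_set_matches_brute_force(self, scenario, peaklists):
        recs, _ = csp_table(peaklists["M"], peaklists["Z"])
        flagged = flag_local_sites(recs, scenario.structure, cutoff=8.0)
        struct = scenario.structure
        for r in flagged:
            xyz = struct.methyl_coords[r.site]
            d_mut = min(
                np.linalg.norm(xyz - p) for _, p in struct.mutation_points
            )
            d_lig = min(np.linalg.norm(xyz - p) for p in struct.ligand_atoms)
            if d_mut <= 8.0:
                assert r.excluded and r.exclusion_reason == "near_mutation"
            elif d_lig <= 8.0:
                assert r.excluded and r.exclusion_reason == "near_ligand"
            else:
                assert not r.excluded

    def test_order_invariance(self, scenario, peaklists):
        recs1, _ = csp_table(peaklists["M"], peaklists["Z"])
        recs2, _ = csp_table(peaklists["M"], peaklists["Z"])
        recs2 = list(reversed(recs2))
        f1 = flag_local_sites(recs1, scenario.structure)
        f2 = flag_local_sites(recs2, scenario.structure)
        m1 = {r.site: (r.excluded, r.exclusion_reason) for r in f1}
        m2 = {r.site: (r.excluded, r.exclusion_reason) for r in f2}
        assert m1 == m2

    def test_site_absent_from_structure_flagged_untraced(self, scenario, peaklists):
        recs, _ = csp_table(peaklists["M"], peaklists["Z"])
        del_site = recs[0].site
        struct = scenario.structure
        coords = dict(struct.methyl_coords)
        coords.pop(del_site)
        from serpinmr.peaklist_io import StructureModel

        reduced = StructureModel(
            methyl_coords=coords,
            mutation_points=struct.mutation_points,
            ligand_atoms=struct.ligand_atoms,
        )
        with pytest.warns(UserWarning, match="absent"):
            flagged = flag_local_sites(recs, reduced)
        rec = next(r for r in flagged if r.site == del_site)
        assert rec.excluded and rec.exclusion_reason == "untraced"


class TestDoubledPeaks:
    def test_split_peak_flagged(self):
        peaks = [
            MethylPeak(0.70, 12.0, 1, MethylSite(293, "g2", "I")),
            MethylPeak(0.73, 12.0, 1, MethylSite(293, "g2", "I")),
        ]
        with pytest.warns(UserWarning, match="duplicate"):
            pl = PeakList(state_label="M", peaks=peaks)
        assert detect_doubled_peaks(pl, tol_H=0.01) == [MethylSite(293, "g2", "I")]
        assert all(p.doubled_flag for p in pl.peaks)

    def test_single_peaks_unflagged(self, peaklists):
        assert detect_doubled_peaks(peaklists["M"]) == []

    def test_planted_doublets_recovered(self):
        sc = generate_scenario(n_sites=100, seed=9, n_local_sites=0)
        lists = render_peaklists(sc, with_noise=False)
        pl = lists["M"]
        rng = np.random.default_rng(1)
        planted = sorted(rng.choice(len(pl.peaks), 3, replace=False))
        import dataclasses

        extra = []
        for i in planted:
            p = pl.peaks[i]
            extra.append(
                dataclasses.replace(
                    p, delta_H=p.delta_H + 0.05, doubled_flag=True
                )
            )
            pl.peaks[i] = dataclasses.replace(p, doubled_flag=True)
        pl.peaks.extend(extra)
        found = detect_doubled_peaks(pl)
        assert found == sorted(pl.peaks[i].site for i in planted)
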