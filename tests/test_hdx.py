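"""HDX difference analysis, confidence bands, residue projection,
interface calls and the solvent-accessibility filter."""

import numpy as np
import pytest

from dutstl import hdx, synth
from dutstl.io import PeptideUptakeRecord, ROLE_RIGID, StructureModel


def records_for(pid, start, end, free_vals, bound_vals, time=1.0):
    recs = []
    for i, v in enumerate(free_vals, start=1):
        recs.append(PeptideUptakeRecord("x", pid, start, end, "free", time, i, v))
    for i, v in enumerate(bound_vals, start=1):
        recs.append(PeptideUptakeRecord("x", pid, start, end, "bound", time, i, v))
    return recs


class TestPeptideDeltas:
    def test_identical_states_give_zero(self):
        recs = records_for(1, 10, 20, [2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        (d,) = hdx.peptide_deltas(recs)
        assert d.accumulated == 0.0

    def test_constant_offset_accumulates_over_times(self):
        recs = []
        for t in (1.0, 10.0, 100.0):
            recs += records_for(1, 10, 20, [2.0] * 3, [1.6] * 3, time=t)
        (d,) = hdx.peptide_deltas(recs)
        assert d.accumulated == pytest.approx(-1.2)

    def test_low_replicate_flagged(self):
        recs = records_for(1, 10, 20, [2.0], [1.5, 1.6])
        (d,) = hdx.peptide_deltas(recs)
        assert d.low_rep

    def test_unpaired_time_dropped(self):
        recs = records_for(1, 10, 20, [2.0, 2.1], [1.5, 1.6], time=1.0)
        recs += [PeptideUptakeRecord("x", 1, 10, 20, "free", 10.0, 1, 3.0)]
        (d,) = hdx.peptide_deltas(recs)
        assert list(d.times) == [1.0]


class TestConfidenceBand:
    def test_zero_replicate_scatter_gives_zero_band(self):
        recs = []
        for pid in range(1, 6):
            recs += records_for(pid, pid * 10, pid * 10 + 8, [2.0] * 3, [2.0] * 3)
        per_time, acc = hdx.confidence_band(hdx.peptide_deltas(recs))
        assert per_time[1.0] == 0.0 and acc == 0.0

    def test_known_scatter_matches_pooled_formula(self):
        # every peptide SD = 0.1 Da, n = 3 both states:
        # half-width = 1.96 * 0.1 * sqrt(2/3) = 0.160 Da
        offsets = np.array([-0.1, 0.0, 0.1])   # sample SD exactly 0.1
        recs = []
        for pid in range(1, 8):
            recs += records_for(pid, pid * 10, pid * 10 + 8,
                                list(2.0 + offsets), list(1.0 + offsets))
        per_time, acc = hdx.confidence_band(hdx.peptide_deltas(recs))
        expect = 1.959963985 * 0.1 * np.sqrt(2.0 / 3.0)
        assert per_time[1.0] == pytest.approx(expect, rel=1e-6)
        assert acc == pytest.approx(expect, rel=1e-6)  # single time here

    def test_too_few_peptides_rejected(self):
        recs = records_for(1, 10, 20, [2.0] * 3, [1.5] * 3)
        with pytest.raises(ValueError, match="5"):
            hdx.confidence_band(hdx.peptide_deltas(recs))


class TestResidueProjection:
    def test_single_peptide_spreads_to_span_minus_first_two(self):
        recs = []
        for t in (1.0, 10.0, 100.0):
            recs += records_for(1, 10, 20, [2.0] * 3, [2.0 - 1.0 / 3.0] * 3, time=t)
        prof = hdx.residue_projection(hdx.peptide_deltas(recs), 30, 0.2)
        vals = {p.residue: p for p in prof}
        for res in range(12, 21):
            assert vals[res].mean_dmass == pytest.approx(-1.0)
            assert vals[res].call == "protected"
        assert vals[11].call == "no-data"
        assert vals[21].call == "no-data"

    def test_overlapping_peptides_average(self):
        recs = records_for(1, 10, 20, [2.0] * 3, [1.0] * 3)
        recs += records_for(2, 15, 25, [2.0] * 3, [1.5] * 3)
        prof = hdx.residue_projection(hdx.peptide_deltas(recs), 30, 10.0)
        vals = {p.residue: p.mean_dmass for p in prof}
        assert vals[18] == pytest.approx(-0.75)   # covered by both
        assert vals[12] == pytest.approx(-1.0)    # first peptide only

    def test_projection_linear_in_deltas(self):
        rng = np.random.default_rng(0)
        recs = []
        for pid in range(1, 7):
            start = pid * 5
            recs += records_for(pid, start, start + 9,
                                list(rng.normal(2, 0.1, 3)), list(rng.normal(1.5, 0.1, 3)))
        deltas = hdx.peptide_deltas(recs)
        prof1 = hdx.residue_projection(deltas, 60, 0.0)
        for d in deltas:
            d.dmass = 2.0 * d.dmass
        prof2 = hdx.residue_projection(deltas, 60, 0.0)
        for a, b in zip(prof1, prof2):
            if a.coverage:
                assert b.mean_dmass == pytest.approx(2.0 * a.mean_dmass, rel=1e-12)


class TestCallInterface:
    def _profile(self, significant, length=60, nodata=()):
        prof = []
        for res in range(1, length + 1):
            if res in nodata:
                prof.append(hdx.ResidueDeltaProfile(res, np.nan, 0, (-1, 1), "no-data"))
            elif res in significant:
                prof.append(hdx.ResidueDeltaProfile(res, -2.0, 2, (-1, 1), "protected"))
            else:
                prof.append(hdx.ResidueDeltaProfile(res, 0.0, 2, (-1, 1), "ns"))
        return prof

    def test_gap_within_tolerance_merges(self):
        sig = set(range(40, 45)) | set(range(46, 51))
        imap = hdx.call_interface(self._profile(sig), gap_tolerance=2)
        assert [(a, b) for a, b, _ in imap.segments] == [(40, 50)]

    def test_no_significant_residues_empty_map(self):
        imap = hdx.call_interface(self._profile(set()))
        assert imap.segments == [] and imap.eligible == set()

    def test_no_data_gaps_bridged(self):
        sig = {40, 41, 46, 47}
        imap = hdx.call_interface(self._profile(sig, nodata={42, 43, 44, 45}),
                                  gap_tolerance=2)
        assert [(a, b) for a, b, _ in imap.segments] == [(40, 47)]

    def test_independent_of_input_order(self):
        rng = np.random.default_rng(1)
        recs = []
        for pid in range(1, 8):
            start = pid * 6
            recs += records_for(pid, start, start + 9,
                                list(rng.normal(2, 0.05, 3)),
                                list(rng.normal(1.0, 0.05, 3)))
        deltas = hdx.peptide_deltas(recs)
        prof = hdx.residue_projection(deltas, 60, 0.1)
        a = hdx.call_interface(prof)
        b = hdx.call_interface(list(reversed(prof)))
        assert a.segments == b.segments


class TestInterfaceRecovery:
    def test_seeded_interfaces_recovered(self):
        spec = synth.HdxSimSpec(length=152, protection_factor=50.0,
                                noise_sd_da=0.05)
        free, bound, _ = synth.simulate_hdx_experiment(
            spec, [(34, 50), (89, 110)], seed=3)
        deltas = hdx.peptide_deltas(free + bound)
        _, acc = hdx.confidence_band(deltas)
        prof = hdx.residue_projection(deltas, 152, acc)
        imap = hdx.call_interface(prof)
        protected = [(a, b) for a, b, d in imap.segments if d == "protected"]
        # every seeded interface lies inside one recovered segment ...
        for lo, hi in ((34, 50), (89, 110)):
            assert any(a <= lo and hi <= b for a, b in protected)
        # ... and every segment overlaps a seeded interface (the peptide
        # footprint limits boundary sharpness to roughly one peptide)
        for a, b in protected:
            assert any(a <= hi and lo <= b for lo, hi in ((34, 50), (89, 110)))
            assert min(abs(a - 34), abs(a - 89)) <= spec.peptide_length
            assert min(abs(b - 50), abs(b - 110)) <= spec.peptide_length

    def test_moderate_protection_still_detected(self):
        # invariant: protection factor >= 20 at noise <= 0.1 Da recovers
        # all covered interface residues
        spec = synth.HdxSimSpec(length=100, protection_factor=20.0,
                                noise_sd_da=0.1)
        free, bound, _ = synth.simulate_hdx_experiment(spec, [(40, 60)], seed=9)
        deltas = hdx.peptide_deltas(free + bound)
        _, acc = hdx.confidence_band(deltas)
        prof = hdx.residue_projection(deltas, 100, acc)
        by_res = {p.residue: p for p in prof}
        for res in range(40, 61):
            if by_res[res].coverage >= 2:
                assert by_res[res].call == "protected"


def test_null_experiment_false_positive_rate():
    """With no seeded protection the significant fraction stays below the
    level implied by the 95% band (Monte-Carlo calibration)."""
    fracs = []
    for seed in range(200):
        spec = synth.HdxSimSpec(length=150, noise_sd_da=0.05,
                                protection_factor=1.0)
        free, bound, _ = synth.simulate_hdx_experiment(spec, [], seed=seed)
        deltas = hdx.peptide_deltas(free + bound)
        _, acc = hdx.confidence_band(deltas)
        prof = hdx.residue_projection(deltas, 150, acc)
        n_cov = sum(1 for p in prof if p.call != "no-data")
        n_sig = sum(1 for p in prof if p.call in ("protected", "deprotected"))
        fracs.append(n_sig / n_cov)
    assert np.mean(fracs) <= 0.07


class TestSasa:
    def test_isolated_bead_closed_form(self):
        m = StructureModel(["A"], np.array([1]), ["ALA"], np.zeros((1, 3)),
                           [ROLE_RIGID])
        area = hdx.sasa_per_residue(m, probe=1.4)[("A", 1)]
        assert area == pytest.approx(4.0 * np.pi * 4.8 ** 2, rel=1e-3)

    def test_enclosed_bead_has_no_accessible_surface(self):
        # dense shell of beads around the origin
        rng = np.random.default_rng(0)
        shell = []
        for theta in np.linspace(0, np.pi, 14):
            for phi in np.linspace(0, 2 * np.pi, 28, endpoint=False):
                shell.append([5.5 * np.sin(theta) * np.cos(phi),
                              5.5 * np.sin(theta) * np.sin(phi),
                              5.5 * np.cos(theta)])
        shell = np.array(shell) + rng.normal(0, 1e-3, (len(shell), 3))
        xyz = np.vstack([[0.0, 0.0, 0.0], shell])
        m = StructureModel(["A"] * len(xyz), np.arange(1, len(xyz) + 1),
                           ["ALA"] * len(xyz), xyz, [ROLE_RIGID] * len(xyz))
        assert hdx.sasa_per_residue(m)[("A", 1)] == pytest.approx(0.0, abs=1e-6)

    def test_sphere_sampling_converged(self, small_complex):
        _, trimer, _ = small_complex
        coarse = hdx.sasa_per_residue(trimer, points=240)
        fine = hdx.sasa_per_residue(trimer, points=960)
        total_c = sum(coarse.values())
        total_f = sum(fine.values())
        assert total_c == pytest.approx(total_f, rel=0.03)

    def test_identical_coordinates_rejected(self):
        xyz = np.zeros((2, 3))
        m = StructureModel(["A", "A"], np.array([1, 2]), ["ALA"] * 2, xyz,
                           [ROLE_RIGID] * 2)
        with pytest.raises(ValueError, match="overlap"):
            hdx.sasa_per_residue(m)


class TestSasaFilter:
    def test_zero_cutoff_keeps_all_segment_residues(self, small_complex):
        _, trimer, _ = small_complex
        areas = hdx.sasa_per_residue(trimer)
        imap = hdx.InterfaceMap("t", segments=[(8, 13, "protected")],
                                eligible=set(range(8, 14)))
        out = hdx.filter_interface_by_sasa(imap, areas, cutoff=0.0)
        assert out.eligible == set(range(8, 14))

    def test_all_buried_empties_eligible_set(self):
        imap = hdx.InterfaceMap("t", segments=[(1, 3, "protected")],
                                eligible={1, 2, 3})
        sasa = {("A", 1): 0.0, ("A", 2): 5.0, ("A", 3): 9.9}
        out = hdx.filter_interface_by_sasa(imap, sasa, cutoff=10.0)
        assert out.eligible == set()
        assert out.segments == imap.segments     # reporting unchanged

    def test_surface_patch_survives_filter(self, small_complex):
        # the generator puts the interface patch on the chain surface, so
        # most of it must remain eligible at the 10 A^2 cutoff
        _, trimer, _ = small_complex
        areas = hdx.sasa_per_residue(trimer)
        imap = hdx.InterfaceMap("t", segments=[(8, 13, "protected")],
                                eligible=set(range(8, 14)))
        out = hdx.filter_interface_by_sasa(imap, areas, cutoff=10.0, chain="A")
        assert len(out.eligible) >= 4
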