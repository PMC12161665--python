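"""Domain types and file I/O."""

import numpy as np
import pytest

from aggpop import (Frame, IsomerRecord, MoleculeSpec, PopulationTable,
                    ThermoContext, phenol_spec, read_frames, read_isomer_table,
                    write_spectrum, write_xyz)
from aggpop.core_model import read_spectrum
from aggpop.spectra import SpectrumGrid
from aggpop.synth_fixtures import SceneConfig, generate_scene


class TestMoleculeSpec:
    def test_phenol_groups(self):
        spec = phenol_spec()
        assert spec.n_atoms == 13
        assert spec.group("hydroxyl").atom_indices == (11, 12)
        assert len(spec.group("aromatic-ring").atom_indices) == 6

    def test_hydroxyl_must_be_oh(self):
        with pytest.raises(ValueError, match="hydroxyl"):
            MoleculeSpec("bad", ("C", "C"), groups=(
                __import__("aggpop").FunctionalGroup("h", "hydroxyl", (0, 1)),))

    def test_index_out_of_range(self):
        from aggpop import FunctionalGroup
        with pytest.raises(ValueError, match="out of range"):
            MoleculeSpec("bad", ("O", "H"),
                         groups=(FunctionalGroup("h", "hydroxyl", (0, 5)),))


class TestFrame:
    def test_volume_from_box(self):
        fr = Frame(0, np.zeros((1, 3)), np.array([10.0, 20.0, 30.0]),
                   np.array([0]), ["x"])
        assert fr.volume_L == pytest.approx(6000e-27)

    def test_bad_box_rejected(self):
        with pytest.raises(ValueError, match="box"):
            Frame(0, np.zeros((1, 3)), np.array([1.0, -1.0, 1.0]),
                  np.array([0]), ["x"])


class TestFrameIO:
    def test_xyz_round_trip_preserves_coordinates(self, tmp_path, specs):
        cfg = SceneConfig(box=(40.0,) * 3, aggregates={(2, "OH-bonded"): 1},
                          n_monomers=2, n_solvent=5, seed=5)
        frames, _, _ = generate_scene(cfg)
        path = tmp_path / "scene.xyz"
        write_xyz(frames, specs, path)
        layout = [("phenol", 4), ("solvent", 5)]
        back = read_frames(path, "xyz", specs, layout)
        assert len(back) == 1
        np.testing.assert_allclose(back[0].coords, frames[0].coords, atol=1e-5)
        np.testing.assert_allclose(back[0].box, frames[0].box, atol=1e-5)
        assert back[0].volume_L == pytest.approx(frames[0].volume_L)

    def test_two_frame_xyz_structure(self, tmp_path, specs):
        cfg = SceneConfig(box=(50.0,) * 3, aggregates={}, n_monomers=3,
                          n_solvent=10, seed=1, n_frames=2)
        frames, _, _ = generate_scene(cfg)
        path = tmp_path / "two.xyz"
        write_xyz(frames, specs, path)
        back = read_frames(path, "xyz", specs, [("phenol", 3), ("solvent", 10)])
        assert len(back) == 2
        assert all(f.n_molecules == 13 for f in back)

    def test_gro_box_in_nm(self, tmp_path):
        spec = MoleculeSpec("atom", ("Ar",))
        gro = ("one atom\n    1\n"
               "    1ATM     AR    1   0.500   0.500   0.500\n"
               "  12.00000  12.00000  12.00000\n")
        p = tmp_path / "box.gro"
        p.write_text(gro)
        frames = read_frames(p, "gro", {"atom": spec}, [("atom", 1)])
        assert frames[0].volume_L == pytest.approx(1.728e-21)
        np.testing.assert_allclose(frames[0].coords[0], [5.0, 5.0, 5.0])

    def test_truncated_second_frame_names_frame(self, tmp_path, specs):
        spec = MoleculeSpec("atom", ("Ar",))
        text = ('2\nLattice="10 0 0 0 10 0 0 0 10"\nAr 0 0 0\nAr 1 1 1\n'
                '2\nLattice="10 0 0 0 10 0 0 0 10"\nAr 0 0 0\n')
        p = tmp_path / "bad.xyz"
        p.write_text(text)
        with pytest.raises(ValueError, match="frame 1"):
            read_frames(p, "xyz", {"atom": spec}, [("atom", 2)])

    def test_missing_box_is_an_error(self, tmp_path):
        spec = MoleculeSpec("atom", ("Ar",))
        p = tmp_path / "nobox.xyz"
        p.write_text("1\nno box here\nAr 0 0 0\n")
        with pytest.raises(ValueError, match="box"):
            read_frames(p, "xyz", {"atom": spec}, [("atom", 1)])


class TestIsomerRecord:
    def test_imaginary_mode_rejected(self):
        with pytest.raises(ValueError, match="imaginary"):
            IsomerRecord("x", 1, 0.0, 0.0, [-25.0, 3000.0], [1.0, 1.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="frequencies"):
            IsomerRecord("x", 1, 0.0, 0.0, [3000.0], [1.0, 2.0])

    def test_frequencies_sorted(self):
        r = IsomerRecord("x", 1, 0.0, 0.0, [3650.0, 50.0], [5.0, 80.0])
        assert list(r.frequencies) == [50.0, 3650.0]


class TestIsomerTable:
    def test_read_valid_and_defaults(self, tmp_path, caplog):
        doc = """
isomers:
  - {label: a, size: 1, e_elec: -10.0, dg_solv: -1.0,
     frequencies: [50, 3650], intensities: [5, 80], degeneracy: 2, mass: 94.1}
  - {label: b, size: 2, e_elec: -20.0, dg_solv: -2.0, pattern: OH-bonded,
     frequencies: [3600], intensities: [100], mass: 188.2,
     inertia: [100, 200, 300]}
"""
        p = tmp_path / "isomers.yaml"
        p.write_text(doc)
        import logging
        with caplog.at_level(logging.WARNING):
            recs = read_isomer_table(p)
        assert [r.label for r in recs] == ["a", "b"]
        assert recs[0].degeneracy == 2
        assert recs[1].degeneracy == 1
        assert "degeneracy" in caplog.text  # defaulting is announced

    def test_hartree_conversion(self, tmp_path):
        doc = """
energy_unit: hartree
isomers:
  - {label: a, size: 1, e_elec: -1.0, dg_solv: 0.0,
     frequencies: [], intensities: [], mass: 94.1}
"""
        p = tmp_path / "h.yaml"
        p.write_text(doc)
        recs = read_isomer_table(p)
        assert recs[0].e_elec == pytest.approx(-627.5094740631)

    def test_negative_frequency_rejected(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("isomers:\n  - {label: z, size: 1, e_elec: 0, dg_solv: 0,\n"
                     "     frequencies: [-25], intensities: [1]}\n")
        with pytest.raises(ValueError, match="z"):
            read_isomer_table(p)


class TestSpectrumIO:
    def test_transmittance_of_zero_absorbance(self, tmp_path):
        grid = SpectrumGrid(np.array([1.0, 2.0, 3.0]), np.zeros(3))
        p = tmp_path / "t.dat"
        write_spectrum(grid, p, mode="transmittance")
        _, vals, meta = read_spectrum(p)
        np.testing.assert_allclose(vals, 1.0)
        assert meta["mode"] == "transmittance"

    def test_decadic_law(self, tmp_path):
        grid = SpectrumGrid(np.array([1.0, 2.0]), np.array([1.0, 0.0]))
        p = tmp_path / "t.dat"
        write_spectrum(grid, p, mode="transmittance")
        _, vals, _ = read_spectrum(p)
        np.testing.assert_allclose(vals, [0.1, 1.0])

    def test_round_trip_six_significant_digits(self, tmp_path):
        w = np.linspace(2800, 3800, 101)
        v = np.exp(-((w - 3300) / 100.0) ** 2) * 123.456
        grid = SpectrumGrid(w, v)
        p = tmp_path / "a.dat"
        write_spectrum(grid, p)
        w2, v2, _ = read_spectrum(p)
        np.testing.assert_allclose(w2, w, rtol=1e-6)
        np.testing.assert_allclose(v2, v, rtol=1e-5)


class TestPopulationTable:
    def test_populations_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            PopulationTable("C/d", {2: {"a": 0.6, "b": 0.6}})

    def test_as_frame_long_form(self):
        t = PopulationTable("Q/s", {2: {"a": 0.25, "b": 0.75}})
        df = t.as_frame()
        assert set(df.columns) == {"size", "pattern", "population", "provenance"}
        assert df["population"].sum() == pytest.approx(1.0)


def test_thermo_context_validation():
    with pytest.raises(ValueError):
        ThermoContext(temperature=-1.0)
    with pytest.raises(ValueError):
        ThermoContext(scale_spectra=0.5)
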