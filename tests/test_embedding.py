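"""Templates, constrained embedding, conformer counting and clustering."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from rdkit import Chem

from heckregio.embedding import (
    Conformer,
    butina_cluster,
    cluster_unique,
    count_conformers,
    embed_conformers,
    heavy_atom_rmsd,
)
from heckregio.errors import TemplateError
from heckregio.templates import load_template


class TestTemplates:
    def test_neutral_bromide_substitution(self):
        t = load_template("neutral", "Br", "cis")
        assert "Br" in t.symbols
        pd, x = t.coords[t.symbols.index("Pd")], t.coords[t.symbols.index("Br")]
        assert np.linalg.norm(x - pd) == pytest.approx(2.5, abs=1e-6)

    def test_neutral_chloride_is_identity(self):
        t = load_template("neutral", "Cl", "cis")
        assert "Cl" in t.symbols
        assert np.linalg.norm(t.coords[2] - t.coords[0]) == pytest.approx(2.4)

    def test_triflate_attaches_through_oxygen(self):
        t = load_template("neutral", "OTf", "trans")
        assert "O" in t.symbols and "Cl" not in t.symbols

    def test_cationic_has_no_halide_and_two_phosphines(self):
        t = load_template("cationic", "I")
        assert t.symbols.count("P") == 2
        assert not set(t.symbols) & {"Cl", "Br", "I"}

    def test_cis_and_trans_differ_in_x_position(self):
        cis = load_template("neutral", "Cl", "cis")
        trans = load_template("neutral", "Cl", "trans")
        # angle C-Pd-X: 90 deg cis, 180 deg trans
        def angle(t):
            c, pd, x = t.coords[1], t.coords[0], t.coords[2]
            u, v = c - pd, x - pd
            return np.degrees(
                np.arccos(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
            )
        assert angle(cis) == pytest.approx(90, abs=1)
        assert angle(trans) == pytest.approx(180, abs=1)

    @pytest.mark.parametrize(
        "pathway,lg,variant",
        [("neutral", "At", "cis"), ("sigma", "Cl", None), ("neutral", "Cl", "syn")],
    )
    def test_invalid_requests_rejected(self, pathway, lg, variant):
        with pytest.raises(TemplateError):
            load_template(pathway, lg, variant)


class TestCountConformers:
    @pytest.mark.parametrize("n_rot,expected", [(0, 1), (5, 16), (26, 79), (27, 80), (40, 80)])
    def test_formula(self, n_rot, expected):
        assert count_conformers(n_rot) == expected

    @given(st.integers(min_value=0, max_value=60))
    def test_nondecreasing_and_capped(self, n_rot):
        assert count_conformers(n_rot) <= 80
        assert count_conformers(n_rot + 1) >= count_conformers(n_rot)
        assert count_conformers(n_rot) == min(1 + 3 * n_rot, 80)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            count_conformers(-1)


class TestEmbedding:
    def test_template_atoms_pinned(self, styrene_specs):
        spec = styrene_specs[0]
        t = load_template(spec.pathway, "Cl", spec.geometry_variant)
        [conf] = embed_conformers(spec, t, 1, seed=11)
        match = t.match(conf.mol)
        for t_idx, mol_idx in enumerate(match):
            assert np.allclose(conf.coords[mol_idx], t.coords[t_idx], atol=1e-4)

    def test_reproducible_for_fixed_seed(self, styrene_specs):
        spec = styrene_specs[2]
        t = load_template(spec.pathway, "Cl", spec.geometry_variant)
        a = embed_conformers(spec, t, 4, seed=7)
        b = embed_conformers(spec, t, 4, seed=7)
        assert len(a) == len(b) >= 1
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.coords, cb.coords)

    def test_neutral_beta_complex_embeds(self, styrene_specs):
        spec = next(
            s
            for s in styrene_specs
            if s.pathway == "neutral" and s.regiochemistry == "beta"
        )
        t = load_template("neutral", "Cl", spec.geometry_variant)
        confs = embed_conformers(spec, t, 16, seed=3)
        assert len(confs) >= 1
        assert all(np.isfinite(c.coords).all() for c in confs)

    def test_mismatched_template_raises(self, styrene_specs):
        neutral = next(s for s in styrene_specs if s.pathway == "neutral")
        cationic_template = load_template("cationic", None)
        with pytest.raises(TemplateError):
            embed_conformers(neutral, cationic_template, 1, seed=1)


def _fake_conformers(coord_sets):
    """Conformers of a 4-heavy-atom chain with fabricated coordinates."""
    mol = Chem.AddHs(Chem.MolFromSmiles("CCCC"))
    out = []
    for i, heavy in enumerate(coord_sets):
        coords = np.zeros((mol.GetNumAtoms(), 3))
        coords[:4] = heavy
        # park hydrogens far away but identically in all conformers
        coords[4:] = 100.0 + np.arange(mol.GetNumAtoms() - 4)[:, None]
        out.append(Conformer("fake", mol, coords, seed=0, index=i))
    return out


BASE = np.array([[0.0, 0, 0], [1.5, 0, 0], [3.0, 0, 0], [4.5, 0, 0]])


class TestRmsdAndClustering:
    def test_rigid_motion_gives_zero_rmsd(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(6, 3))
        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        moved = pts @ rot.T + np.array([3.0, -2.0, 1.0])
        assert heavy_atom_rmsd(pts, moved) == pytest.approx(0.0, abs=1e-9)

    def test_rmsd_matches_rdkit_alignment(self):
        """Independent cross-check against RDKit's conformer alignment
        with the identity atom map."""
        from rdkit.Chem import rdMolAlign

        mol = Chem.MolFromSmiles("CCCC")
        rng = np.random.default_rng(5)
        a = BASE + rng.normal(scale=0.3, size=BASE.shape)
        b = BASE + rng.normal(scale=0.3, size=BASE.shape)
        for conf_pts in (a, b):
            conf = Chem.Conformer(4)
            for i, p in enumerate(conf_pts):
                conf.SetAtomPosition(i, tuple(float(x) for x in p))
            mol.AddConformer(conf, assignId=True)
        rd = rdMolAlign.AlignMol(
            mol, mol, prbCid=1, refCid=0, atomMap=[(i, i) for i in range(4)]
        )
        assert heavy_atom_rmsd(a, b) == pytest.approx(rd, abs=1e-6)

    def test_identical_copies_collapse_to_one_centroid(self):
        confs = _fake_conformers([BASE] * 5)
        assert len(cluster_unique(confs, 0.5)) == 1

    def test_threshold_straddling_pair(self):
        """A pair separated by a measured RMSD d clusters to one centroid
        for thresholds above d and two below it."""
        rng = np.random.default_rng(9)
        other = BASE + rng.normal(scale=0.5, size=BASE.shape)
        confs = _fake_conformers([BASE, other])
        d = heavy_atom_rmsd(
            confs[0].coords, confs[1].coords, confs[0].heavy_indices
        )
        assert 0.1 < d < 5.0
        assert len(cluster_unique(confs, d * 1.1)) == 1
        assert len(cluster_unique(confs, d * 0.9)) == 2

    def test_clustering_output_subset_and_idempotent(self):
        rng = np.random.default_rng(4)
        sets = [BASE + rng.normal(scale=0.4, size=BASE.shape) for _ in range(12)]
        confs = _fake_conformers(sets)
        centroids = cluster_unique(confs, 0.5)
        assert set(id(c) for c in centroids) <= set(id(c) for c in confs)
        again = cluster_unique(centroids, 0.5)
        assert [c.index for c in again] == [c.index for c in centroids]

    def test_every_input_within_threshold_of_some_centroid(self):
        rng = np.random.default_rng(8)
        sets = [BASE + rng.normal(scale=0.6, size=BASE.shape) for _ in range(15)]
        confs = _fake_conformers(sets)
        threshold = 0.7
        centroids = cluster_unique(confs, threshold)
        heavy = confs[0].heavy_indices
        for c in confs:
            assert any(
                heavy_atom_rmsd(c.coords, cen.coords, heavy) <= threshold + 1e-9
                for cen in centroids
            )

    @given(st.integers(min_value=1, max_value=12), st.integers(min_value=0, max_value=10))
    def test_butina_partition_properties(self, n, seed):
        """Butina output is a partition; centroids are processed in
        descending neighbour count."""
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 3, size=(n, 1))
        dist = np.abs(pts - pts.T)
        clusters = butina_cluster(dist, 1.0)
        members = [m for _, ms in clusters for m in ms]
        assert sorted(members) == list(range(n))
        for centroid, ms in clusters:
            assert centroid in ms
            assert all(dist[centroid, m] <= 1.0 for m in ms)
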