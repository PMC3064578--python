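"""CAPRI statistics: RMSD oracles, star classification, hypergeometric enrichment."""

from math import comb

import numpy as np
import pytest

from cport import (
    DecoyEnsemble,
    best_of_mappings,
    classify_stars,
    enrichment_pvalue,
    evaluate_decoy,
    evaluate_ensemble,
    first_star_rank,
    fnat,
    irmsd,
    kabsch,
    lrmsd,
    make_decoys,
    random_rigid_transforms,
    rotation_matrix,
    toy_complex,
)

from conftest import rid


def quaternion_superpose(mobile, target):
    """Independent superposition oracle (Horn's quaternion method)."""
    P = np.asarray(mobile, float)
    Q = np.asarray(target, float)
    p = P - P.mean(axis=0)
    q = Q - Q.mean(axis=0)
    M = p.T @ q
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    vals, vecs = np.linalg.eigh(K)
    w, x, y, z = vecs[:, np.argmax(vals)]
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = Q.mean(axis=0) - R @ P.mean(axis=0)
    return R, t


@pytest.fixture
def reference():
    return toy_complex(20, seed=11)


class TestKabsch:
    def test_matches_quaternion_oracle(self, rng):
        for _ in range(20):
            P = rng.normal(size=(12, 3))
            R_true = rotation_matrix(rng.normal(size=3), rng.uniform(0, np.pi))
            Q = P @ R_true.T + rng.normal(size=3) + 0.01 * rng.normal(size=(12, 3))
            R1, t1 = kabsch(P, Q)
            R2, t2 = quaternion_superpose(P, Q)
            assert np.allclose(R1, R2, atol=1e-6)
            assert np.allclose(t1, t2, atol=1e-6)

    def test_proper_rotation_under_near_reflection(self, rng):
        P = rng.normal(size=(6, 3))
        Q = P * np.array([1.0, 1.0, -1.0])  # mirrored target
        R, _ = kabsch(P, Q)
        assert np.linalg.det(R) == pytest.approx(1.0)


class TestRmsd:
    def test_identity_decoy_zero(self, reference):
        assert lrmsd(reference, reference) == pytest.approx(0.0, abs=1e-9)
        assert irmsd(reference, reference) == pytest.approx(0.0, abs=1e-9)
        assert fnat(reference, reference) == 1.0

    def test_pure_translation_lrmsd_analytic(self, reference):
        for t in [(3, 0, 0), (0, -2.5, 1.0), (1, 1, 1)]:
            decoy = reference.transformed(translation=t, chains=["B"])
            assert lrmsd(decoy, reference) == pytest.approx(np.linalg.norm(t), abs=1e-9)

    def test_invariance_under_global_rigid_motion(self, reference, rng):
        decoy = reference.transformed(translation=(2.0, 0, 0), chains=["B"])
        base_l, base_i = lrmsd(decoy, reference), irmsd(decoy, reference)
        for _ in range(5):
            R = rotation_matrix(rng.normal(size=3), rng.uniform(0, np.pi))
            moved = decoy.transformed(rotation=R, translation=rng.normal(size=3) * 10)
            assert lrmsd(moved, reference) == pytest.approx(base_l, abs=1e-6)
            assert irmsd(moved, reference) == pytest.approx(base_i, abs=1e-6)

    def test_rotation_about_ligand_centroid_closed_form(self, reference):
        """A 180-degree rotation about an axis through the ligand centroid
        gives l-RMSD = 2 * RMS(perpendicular distance to the axis)."""
        from cport.structure import BACKBONE_ATOMS

        axis = np.array([0.0, 0.0, 1.0])
        R = rotation_matrix(axis, np.pi)
        decoy = reference.transformed(rotation=R, chains=["B"])
        mask = reference.atom_mask(chains=["B"], atom_names=BACKBONE_ATOMS)
        pts = reference.coords[mask]
        centroid = reference.coords[reference.atom_mask(chains=["B"])].mean(axis=0)
        rel = pts - centroid
        perp = rel[:, :2]  # components perpendicular to z axis
        expected = 2.0 * np.sqrt((perp**2).sum(axis=1).mean())
        # receptor fit is identity (receptor untouched), so l-RMSD is direct
        assert lrmsd(decoy, reference) == pytest.approx(expected, abs=1e-6)

    def test_fnat_partial_contacts(self, reference):
        from cport.structure import residue_contacts

        native = residue_contacts(reference)
        # hinge the ligand about one end of the contact window: near contacts
        # survive, far ones break
        pivot_x = (min(b.residue_number for _, b in native) - 1) * 3.8
        decoy = reference.transformed(
            rotation=rotation_matrix((0, 1, 0), -0.25),
            chains=["B"],
            about=(pivot_x, 0.0, 6.2),
        )
        surviving = residue_contacts(decoy) & native
        assert 0 < len(surviving) < len(native)
        assert fnat(decoy, reference) == pytest.approx(len(surviving) / len(native))

    def test_fnat_separated_zero(self, reference):
        decoy = reference.transformed(translation=(0, 0, 50.0), chains=["B"])
        assert fnat(decoy, reference) == 0.0


class TestStars:
    @pytest.mark.parametrize(
        "i,l,f,apply_fnat,expected",
        [
            (3.5, 12.0, 0.2, True, 1),
            (3.5, 12.0, 0.05, True, 0),
            (3.5, 12.0, 0.05, False, 1),
            (0.8, 0.9, 0.6, True, 3),
            (1.5, 4.0, 0.35, True, 2),
            (1.5, 4.0, 0.2, True, 1),
            (5.0, 11.0, 0.9, True, 0),
            (0.5, 0.5, 0.05, False, 3),
        ],
    )
    def test_classification(self, i, l, f, apply_fnat, expected):
        assert classify_stars(i, l, f, apply_fnat) == expected

    def test_monotone_in_rmsds(self, rng):
        for _ in range(200):
            i1, l1 = rng.uniform(0, 6), rng.uniform(0, 12)
            f = rng.uniform(0, 1)
            s1 = classify_stars(i1, l1, f)
            s2 = classify_stars(i1 + rng.uniform(0, 3), l1 + rng.uniform(0, 5), f)
            assert s2 <= s1


class TestBestOfMappings:
    def make_homodimer_like(self):
        # asymmetric two-chain toy; swapping labels misaligns everything
        return toy_complex(12, seed=4)

    def test_single_mapping_identity(self, reference):
        decoy = reference.transformed(translation=(1.0, 0, 0), chains=["B"])
        direct = evaluate_decoy(decoy, reference, apply_fnat=True)
        mapped = best_of_mappings(decoy, reference, [{"A": "A", "B": "B"}])
        assert mapped.i_rmsd == pytest.approx(direct.i_rmsd, abs=1e-9)

    def test_correct_mapping_wins(self):
        ref = self.make_homodimer_like()
        decoy = ref.transformed(translation=(0.5, 0, 0), chains=["B"])
        good = {"A": "A", "B": "B"}
        swapped = {"A": "B", "B": "A"}
        best = best_of_mappings(decoy, ref, [swapped, good])
        direct = evaluate_decoy(decoy, ref, apply_fnat=True)
        assert best.i_rmsd == pytest.approx(direct.i_rmsd, abs=1e-9)
        assert best.l_rmsd == pytest.approx(direct.l_rmsd, abs=1e-9)

    def test_symmetric_homodimer_swap_indifferent(self):
        """For an exact C2 homodimer, a chain-swapped decoy scores the same
        under either mapping (and is a perfect model of the complex)."""
        import cport
        from cport.capri import apply_chain_mapping

        n = 8
        # chain B is the 180-degree rotation of chain A about a C2 axis
        xs = 3.8 * np.arange(n)
        c = np.array([xs.mean(), 2.0, 0.0])
        coords_a = np.column_stack([xs, np.zeros(n), np.zeros(n)])
        coords_b = np.column_stack([2 * c[0] - xs, 2 * c[1] - np.zeros(n), np.zeros(n)])
        cs = cport.ComplexStructure(
            [rid("A", i + 1) for i in range(n)] + [rid("B", i + 1) for i in range(n)],
            ["ALA"] * (2 * n),
            ["CA"] * (2 * n),
            np.array(["C"] * (2 * n), dtype=object),
            np.vstack([coords_a, coords_b]),
            ("A",),
            ("B",),
        )
        assert len(cport.interface_residues(cs)) > 0
        decoy = apply_chain_mapping(cs, {"A": "B", "B": "A"})  # pure relabel
        identity = {"A": "A", "B": "B"}
        swap = {"A": "B", "B": "A"}
        r1 = best_of_mappings(decoy, cs, [identity], apply_fnat=False)
        r2 = best_of_mappings(decoy, cs, [swap], apply_fnat=False)
        # C2 symmetry makes the relabelled decoy a global isometry of the
        # reference, so both mappings give an essentially perfect model
        assert r1.i_rmsd == pytest.approx(r2.i_rmsd, abs=1e-9)
        assert r1.i_rmsd == pytest.approx(0.0, abs=1e-9)


class TestEnsembleEvaluation:
    def test_planted_star_counts_recovered(self, reference, rng):
        """Synthetic ensemble with known-good poses: star counts are exact."""
        n_native, n_bad = 12, 88
        transforms = [(None, None)] * n_native
        transforms += [
            (rotation_matrix(rng.normal(size=3), rng.uniform(0.5, np.pi)), rng.normal(size=3) * 40)
            for _ in range(n_bad)
        ]
        ensemble = make_decoys(reference, transforms, stage="rigid_body")
        results = evaluate_ensemble(ensemble)
        stars = [r.stars for r in results]
        assert sum(s == 3 for s in stars) == n_native
        assert first_star_rank(results) == 1

    def test_rigid_body_stage_skips_fnat(self, reference):
        decoy = reference.transformed(translation=(0, 3.0, 3.0), chains=["B"])
        ens = DecoyEnsemble(reference, [decoy], stage="rigid_body")
        with_fnat = evaluate_ensemble(ens, apply_fnat=True)[0]
        without = evaluate_ensemble(ens)[0]
        assert without.stars >= with_fnat.stars

    def test_geometry_oracles_on_many_random_decoys(self, reference, rng):
        """l-RMSD of pure translations and rigid invariance over 100 decoys."""
        shifts = [rng.normal(size=3) * rng.uniform(0, 8) for _ in range(100)]
        ensemble = make_decoys(reference, [(None, s) for s in shifts])
        for shift, decoy in zip(shifts, ensemble.decoys):
            assert lrmsd(decoy, reference) == pytest.approx(np.linalg.norm(shift), abs=1e-6)
        # global motion leaves the statistics untouched
        R = rotation_matrix((1, 2, 3), 1.1)
        for decoy, shift in list(zip(ensemble.decoys, shifts))[:10]:
            moved = decoy.transformed(rotation=R, translation=(5, -4, 2))
            assert lrmsd(moved, reference) == pytest.approx(np.linalg.norm(shift), abs=1e-6)


class TestEnrichment:
    def test_select_all_boundary(self):
        p_enrich, p_deplete = enrichment_pvalue(100, 7, 100, 7)
        assert p_enrich == pytest.approx(1.0)
        assert p_deplete == pytest.approx(1.0)

    def test_closed_form_depletion(self):
        # no correct decoy among 400 of 10000 with 10 correct overall
        _, p_deplete = enrichment_pvalue(10_000, 10, 400, 0)
        expected = comb(9990, 400) / comb(10_000, 400)
        assert p_deplete == pytest.approx(expected, rel=1e-9)

    def test_matches_exhaustive_enumeration_small_populations(self, rng):
        for _ in range(30):
            n = int(rng.integers(1, 31))
            k = int(rng.integers(0, n + 1))
            m = int(rng.integers(1, n + 1))
            x = int(rng.integers(0, min(k, m) + 1))
            # enumeration oracle over all possible selections
            total = comb(n, m)
            p_ge = sum(comb(k, j) * comb(n - k, m - j) for j in range(x, min(k, m) + 1) if m - j <= n - k) / total
            p_le = sum(comb(k, j) * comb(n - k, m - j) for j in range(0, x + 1) if m - j <= n - k) / total
            got_ge, got_le = enrichment_pvalue(n, k, m, x)
            assert got_ge == pytest.approx(p_ge, rel=1e-9, abs=1e-12)
            assert got_le == pytest.approx(p_le, rel=1e-9, abs=1e-12)

    def test_tails_share_point_mass(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 200))
            k = int(rng.integers(0, n + 1))
            m = int(rng.integers(1, n + 1))
            x = int(rng.integers(0, min(k, m) + 1))
            p_enrich, p_deplete = enrichment_pvalue(n, k, m, x)
            assert p_enrich + p_deplete >= 1.0 - 1e-12
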