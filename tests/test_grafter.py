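import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cleavescan.structio import Ensemble
from cleavescan.ffenergy import nonbonded_energy
from cleavescan.grafter import ActiveSiteTemplate, fit_ensemble, graft
from cleavescan.fixtures import FixtureSpec, make_peptide, make_receptor


@pytest.fixture(scope="module")
def self_conformer(open_template_module):
    """A capped peptide whose cap carbonyl and first residues align exactly
    with the template's P1 carbonyl and primed residues (self-graft)."""
    template = open_template_module
    pep = template.peptide
    conf = make_peptide("AAAA", "extended", capped=True, chain_id="S")
    # superpose the conformer's fit atoms onto the template's: after graft
    # the fitted atoms must coincide regardless of the starting placement
    return conf


@pytest.fixture(scope="module")
def open_template_module():
    return make_receptor(FixtureSpec(groove="open"))


@pytest.fixture(scope="module")
def blocked_template_module():
    return make_receptor(FixtureSpec(groove="blocked"))


class TestTemplate:
    def test_nine_labelled_residues(self, open_template_module):
        t = open_template_module
        assert sorted(t.p_residues.values()) == list(range(1, 10))
        assert len(t.p_residues) == 9

    def test_scissile_bond_atoms(self, open_template_module):
        t = open_template_module
        ci, ni = t.scissile_bond
        assert t.peptide.atom_names[ci] == "C"
        assert t.peptide.residue_indices[ci] == t.p_residues["P1"]
        assert t.peptide.atom_names[ni] == "N"
        assert t.peptide.residue_indices[ni] == t.p_residues["P1'"]

    def test_wrong_residue_count_rejected(self, open_template_module):
        pep8 = make_peptide("AAAAAAAA", "extended", capped=False, chain_id="T")
        with pytest.raises(ValueError):
            ActiveSiteTemplate.from_structures(
                open_template_module.protease, pep8
            )


class TestGraft:
    def test_fit_atoms_coincide_after_graft(self, open_template_module,
                                            self_conformer):
        t = open_template_module
        c = graft(self_conformer, t)
        s = c.structure
        # cap C/O sit exactly on the deleted P1 carbonyl positions
        cap_c = s.find_atom("S", 0, "C")
        cap_o = s.find_atom("S", 0, "O")
        tfit = np.asarray(t.fit_atoms)
        assert np.abs(s.coords[cap_c] - t.peptide.coords[tfit[0]]).max() < 2e-2
        assert np.abs(s.coords[cap_o] - t.peptide.coords[tfit[1]]).max() < 2e-2

    def test_atom_count_bookkeeping(self, open_template_module, self_conformer):
        t = open_template_module
        c = graft(self_conformer, t)
        p1 = t.p_residues["P1"]
        kept_template = int(
            np.sum(t.peptide.residue_indices <= p1) - 2  # minus C, O of P1
        )
        expected = (
            t.protease.n_atoms + kept_template + self_conformer.n_atoms - 1
        )  # cap methyl consumed by the junction
        assert c.structure.n_atoms == expected
        assert len(c.poi_atoms) == self_conformer.n_atoms - 1

    def test_invariant_under_prior_rigid_transform(self, open_template_module,
                                                   self_conformer):
        t = open_template_module
        c0 = graft(self_conformer, t)
        rot = Rotation.from_rotvec([1.0, 0.3, -0.8])
        moved = self_conformer.with_coords(
            rot.apply(self_conformer.coords) + [3.0, -1.0, 2.0]
        )
        c1 = graft(moved, t)
        assert np.abs(c0.structure.coords - c1.structure.coords).max() < 1e-9

    def test_junction_bond_present(self, open_template_module, self_conformer):
        t = open_template_module
        c = graft(self_conformer, t)
        s = c.structure
        p1_ca = s.find_atom("T", t.p_residues["P1"], "CA")
        cap_c = s.find_atom("S", 0, "C")
        assert (min(p1_ca, cap_c), max(p1_ca, cap_c)) in s.bonds

    def test_missing_fit_atoms_named_in_error(self, open_template_module):
        uncapped = make_peptide("AAAA", "extended", capped=False, chain_id="S")
        with pytest.raises(ValueError, match="C"):
            graft(uncapped, open_template_module)


class TestFitEnsemble:
    def test_clash_free_conformer_retained(self, open_template_module, params,
                                           self_conformer):
        ens = Ensemble(self_conformer, [self_conformer.coords.copy()])
        out = fit_ensemble(ens, open_template_module, params, nterm_span=4)
        assert out[0].retained
        assert out[0].e_interaction < 0

    def test_blocked_groove_rejects(self, blocked_template_module, params,
                                    self_conformer):
        ens = Ensemble(self_conformer, [self_conformer.coords.copy()])
        out = fit_ensemble(ens, blocked_template_module, params, nterm_span=4)
        assert not out[0].retained
        assert out[0].e_interaction > 0

    def test_retained_set_equals_brute_force(self, stitched_small,
                                             open_template_module, params):
        stitched, _, _ = stitched_small
        out = fit_ensemble(stitched, open_template_module, params, nterm_span=5)
        brute = [o.conformer_id for o in out if o.e_interaction < 0]
        assert [o.conformer_id for o in out if o.retained] == brute

    def test_protease_untouched_by_minimization(self, stitched_small,
                                                open_template_module, params):
        stitched, _, _ = stitched_small
        t = open_template_module
        c = graft(stitched.structure(0), t)
        from cleavescan.ffenergy import MinimizerConfig, steepest_descent

        relaxed, _, _ = steepest_descent(
            c.structure, c.poi_atoms, params, MinimizerConfig()
        )
        assert np.array_equal(
            relaxed.coords[c.protease_atoms],
            c.structure.coords[c.protease_atoms],
        )
        assert np.array_equal(
            relaxed.coords[c.template_atoms],
            c.structure.coords[c.template_atoms],
        )

    def test_bulk_energy_is_partial_sum(self, stitched_small,
                                        open_template_module, params):
        """Dropping N-terminal atoms from the POI group removes exactly
        their pair terms: E_bulk + E_nterm = E_interaction."""
        stitched, _, _ = stitched_small
        t = open_template_module
        c = graft(stitched.structure(0), t)
        span = 5
        poi_res = c.structure.residue_indices[c.poi_atoms]
        bulk = c.poi_atoms[poi_res > span]
        nterm = c.poi_atoms[poi_res <= span]
        e_all = nonbonded_energy(c.structure, c.protease_atoms, c.poi_atoms,
                                 params)
        e_bulk = nonbonded_energy(c.structure, c.protease_atoms, bulk, params)
        e_nterm = nonbonded_energy(c.structure, c.protease_atoms, nterm,
                                   params)
        assert e_all == pytest.approx(e_bulk + e_nterm, rel=1e-9)
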