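"""Grafting conformers into a protease active-site template.

The template is a protease structure holding a bound 9-residue substrate
peptide whose residues are labelled P5..P1 and P1'..P4' (Schechter-Berger
nomenclature); the scissile bond joins P1 to P1'.  A conformer — the
protein of interest (POI) with its sampled N-terminal conformation and an
ACE cap standing in for the upstream chain — is placed by superposing its
N-terminal peptide-bond atoms (cap C, O; residue-1 N, H) onto the
template's P1-P1' bond atoms.  The template peptide is then truncated:
everything from the fit atoms through P4' is replaced by the POI, while
the P5..P1 remainder stays as the bound recognition-site stand-in.  The
grafted POI is covalently joined to that remainder (P1 CA to cap C), so
relaxation keeps the substrate anchored in the site the way the
pre-cleavage chain would be.

Cleavability is then read off the protease/POI nonbonded interaction
energy after a short POI-only relaxation: a conformer "fits" iff that
energy is strictly negative.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .structio import Structure, Ensemble
from .ffenergy import (
    EnergyModel,
    ForceFieldParams,
    MinimizerConfig,
    nonbonded_energy,
    steepest_descent,
)
from .stitcher import superpose

P_LABELS = ("P5", "P4", "P3", "P2", "P1", "P1'", "P2'", "P3'", "P4'")


@dataclasses.dataclass
class ActiveSiteTemplate:
    """Protease + bound template peptide with P-site labels.

    ``p_residues`` maps each of the nine labels to a residue index of
    ``peptide``; ``fit_atoms`` are peptide atom indices (C, O of P1; N,
    H-or-CA of P1') used for scissile-bond alignment.
    """

    protease: Structure
    peptide: Structure
    p_residues: dict
    scissile_bond: tuple[int, int]
    fit_atoms: Sequence[int]

    def __post_init__(self):
        if sorted(self.p_residues) != sorted(P_LABELS):
            raise ValueError(f"p_residues must label exactly {P_LABELS}")
        ci, ni = self.scissile_bond
        if (
            self.peptide.atom_names[ci] != "C"
            or self.peptide.atom_names[ni] != "N"
            or self.peptide.residue_indices[ci] != self.p_residues["P1"]
            or self.peptide.residue_indices[ni] != self.p_residues["P1'"]
        ):
            raise ValueError("scissile bond must join C of P1 to N of P1'")

    @classmethod
    def from_structures(
        cls, protease: Structure, peptide: Structure
    ) -> "ActiveSiteTemplate":
        """Label a 9-residue bound peptide P5..P4' in residue order."""
        seq = peptide.sequence(peptide.chain_ids[0])
        if len(seq) != 9:
            raise ValueError(f"template peptide has {len(seq)} residues, need 9")
        p_res = {lab: rid for lab, (rid, _) in zip(P_LABELS, seq)}
        chain = peptide.chain_ids[0]
        c1 = peptide.find_atom(chain, p_res["P1"], "C")
        n1 = peptide.find_atom(chain, p_res["P1'"], "N")
        fit = [c1, peptide.find_atom(chain, p_res["P1"], "O"), n1]
        try:
            fit.append(peptide.find_atom(chain, p_res["P1'"], "H"))
        except KeyError:
            fit.append(peptide.find_atom(chain, p_res["P1'"], "CA"))
        return cls(protease, peptide, p_res, (c1, n1), fit)


@dataclasses.dataclass
class FitOutcome:
    conformer_id: int
    e_interaction: float  # protease <-> whole POI, kJ/mol
    e_bulk_interaction: float  # protease <-> POI minus N-terminal span
    retained: bool
    n_min_steps: int = 0
    failed: bool = False  # non-finite energy (unresolvable overlap)


@dataclasses.dataclass
class GraftedComplex:
    structure: Structure
    protease_atoms: np.ndarray
    template_atoms: np.ndarray  # retained P5..P1 remainder
    poi_atoms: np.ndarray


def _conformer_fit_atoms(conformer: Structure) -> list[int]:
    chain = conformer.chain_ids[0]
    missing = []
    idx = []
    for resid, name in ((0, "C"), (0, "O"), (1, "N")):
        try:
            idx.append(conformer.find_atom(chain, resid, name))
        except KeyError:
            missing.append(f"{resid}/{name}")
    if not missing:
        try:
            idx.append(conformer.find_atom(chain, 1, "H"))
        except KeyError:
            try:
                idx.append(conformer.find_atom(chain, 1, "CA"))
            except KeyError:
                missing.append("1/H|CA")
    if missing:
        raise ValueError(
            "conformer lacks N-terminal fit atoms: " + ", ".join(missing)
        )
    return idx


def graft(conformer: Structure, template: ActiveSiteTemplate) -> GraftedComplex:
    """Superpose a conformer onto the scissile bond and assemble the complex.

    The complex holds, in order: the protease, the template peptide's
    P5..P1 atoms minus the fit atoms (C, O of P1), and the POI conformer
    minus its cap methyl.  The conformer's cap carbonyl takes over the P1
    carbonyl position; its methyl, which would coincide with the P1 CA, is
    consumed by the junction, and a bond from the P1 CA to the cap carbonyl
    carbon restores the pre-cleavage chain connectivity through the
    scissile peptide unit.
    """
    pep = template.peptide
    prot = template.protease
    tfit = np.asarray(template.fit_atoms, dtype=int)
    cfit = np.asarray(_conformer_fit_atoms(conformer), dtype=int)
    rot, t, _ = superpose(conformer.coords[cfit], pep.coords[tfit])
    moved = conformer.coords @ rot.T + t

    p1 = template.p_residues["P1"]
    drop = set(int(i) for i in tfit[:2])  # C, O of P1
    keep_pep = np.array(
        [
            i
            for i in range(pep.n_atoms)
            if pep.residue_indices[i] <= p1 and i not in drop
        ],
        dtype=int,
    )
    # the cap methyl would sit on top of the P1 CA: the junction consumes it
    chain_s = conformer.chain_ids[0]
    try:
        cap_ch3 = conformer.find_atom(chain_s, 0, "CH3")
    except KeyError as exc:
        raise ValueError("conformer lacks an ACE cap methyl") from exc
    keep_poi = np.array(
        [i for i in range(conformer.n_atoms) if i != cap_ch3], dtype=int
    )
    n_prot = prot.n_atoms
    n_keep = len(keep_pep)
    n_poi = len(keep_poi)
    pep_new = {int(i): n_prot + k for k, i in enumerate(keep_pep)}
    poi_new = {int(i): n_prot + n_keep + k for k, i in enumerate(keep_poi)}

    names = np.concatenate(
        [prot.atom_names, pep.atom_names[keep_pep], conformer.atom_names[keep_poi]]
    )
    resids = np.concatenate(
        [prot.residue_indices, pep.residue_indices[keep_pep],
         conformer.residue_indices[keep_poi]]
    )
    resnames = np.concatenate(
        [prot.residue_names, pep.residue_names[keep_pep],
         conformer.residue_names[keep_poi]]
    )
    chains = np.concatenate(
        [
            prot.chain_ids,
            np.full(n_keep, "T", dtype=object),
            np.full(n_poi, "S", dtype=object),
        ]
    )
    coords = np.vstack([prot.coords, pep.coords[keep_pep], moved[keep_poi]])
    elements = np.concatenate(
        [prot.elements, pep.elements[keep_pep], conformer.elements[keep_poi]]
    )
    charges = np.concatenate(
        [prot.charges, pep.charges[keep_pep], conformer.charges[keep_poi]]
    )
    nb_types = np.concatenate(
        [prot.nb_types, pep.nb_types[keep_pep], conformer.nb_types[keep_poi]]
    )

    bonds = set()
    for i, j in prot.bonds:
        bonds.add((i, j))
    for i, j in pep.bonds:
        if i in pep_new and j in pep_new:
            a, b = pep_new[i], pep_new[j]
            bonds.add((min(a, b), max(a, b)))
    for i, j in conformer.bonds:
        if i in poi_new and j in poi_new:
            a, b = poi_new[i], poi_new[j]
            bonds.add((min(a, b), max(a, b)))
    # covalent junction: P1 CA -> POI cap carbonyl C
    chain_t = pep.chain_ids[0]
    p1_ca = pep.find_atom(chain_t, p1, "CA")
    cap_c = poi_new[int(cfit[0])]
    a, b = pep_new[p1_ca], cap_c
    bonds.add((min(a, b), max(a, b)))

    structure = Structure(
        atom_names=names,
        residue_indices=resids,
        residue_names=resnames,
        chain_ids=chains,
        coords=coords,
        elements=elements,
        charges=charges,
        nb_types=nb_types,
        bonds=bonds,
        label=f"{conformer.label}@site",
        validate=False,  # chain relabelling guarantees uniqueness
    )
    return GraftedComplex(
        structure,
        protease_atoms=np.arange(n_prot),
        template_atoms=np.arange(n_prot, n_prot + n_keep),
        poi_atoms=np.arange(n_prot + n_keep, n_prot + n_keep + n_poi),
    )


def fit_ensemble(
    ensemble: Ensemble,
    template: ActiveSiteTemplate,
    params: ForceFieldParams,
    min_cfg: MinimizerConfig | None = None,
    nterm_span: int | None = None,
    include_template_with_protease: bool = False,
) -> list[FitOutcome]:
    """Graft, relax and score every conformer of an ensemble.

    Per conformer: graft into the active site, steepest-descent with only
    the POI atoms mobile (the protease and the bound-tag remainder are
    frozen), then evaluate the protease/POI nonbonded interaction energy.
    A conformer is retained iff that energy is strictly negative.
    ``e_bulk_interaction`` repeats the sum with the POI's N-terminal span
    (residues <= ``nterm_span``, cap included) left out of the POI group —
    the readout used to compare how the protein bodies sit in the site.
    The retained P5..P1 recognition-site residues belong to neither energy
    group by default (they model the bound tag);
    ``include_template_with_protease`` counts them with the enzyme.
    A non-finite energy (atoms driven coincident) marks the outcome failed
    and not retained rather than raising.
    """
    min_cfg = min_cfg or MinimizerConfig()
    if nterm_span is None:
        nterm_span = 0  # exclude only the cap residue from the bulk group
    outcomes: list[FitOutcome] = []
    model: EnergyModel | None = None
    for cid in range(len(ensemble)):
        conformer = ensemble.structure(cid)
        complex_ = graft(conformer, template)
        s = complex_.structure
        if model is None:
            model = EnergyModel(s, params, complex_.poi_atoms)
        enzyme_group = (
            np.concatenate([complex_.protease_atoms, complex_.template_atoms])
            if include_template_with_protease
            else complex_.protease_atoms
        )
        try:
            relaxed, n_steps, _ = steepest_descent(
                s, complex_.poi_atoms, params, min_cfg, model=model
            )
            e_int = nonbonded_energy(
                relaxed, enzyme_group, complex_.poi_atoms, params
            )
            poi_resids = relaxed.residue_indices[complex_.poi_atoms]
            bulk = complex_.poi_atoms[poi_resids > nterm_span]
            e_bulk = nonbonded_energy(
                relaxed, enzyme_group, bulk, params
            )
        except FloatingPointError:
            outcomes.append(
                FitOutcome(cid, float("inf"), float("inf"), False, 0, failed=True)
            )
            continue
        outcomes.append(
            FitOutcome(cid, float(e_int), float(e_bulk), bool(e_int < 0.0),
                       int(n_steps))
        )
    return outcomes
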