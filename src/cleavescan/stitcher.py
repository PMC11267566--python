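"""Ligation of sampled N-terminus conformers onto the rigid protein body.

A conformer is joined to the body by least-squares superposition of four
shared backbone atoms around the junction peptide bond — C and O of the
carbonyl preceding the overlap residue, plus N and H (or CA when the amide
hydrogen is absent) of the overlap residue — followed by atom replacement
at the overlap residue's CA: the peptide contributes everything up to and
including that CA, the body everything after it.  Minor clashes are then
relaxed by a short steepest descent in which only the reattached N-terminal
atoms move, and conformers whose N-terminus/body nonbonded interaction
energy is not negative are discarded.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np

from .structio import Structure, Ensemble, StructureError
from .ffenergy import (
    EnergyModel,
    ForceFieldParams,
    MinimizerConfig,
    energy_filter,
    nonbonded_energy,
    steepest_descent,
)

FIT_RMSD_WARN = 0.05  # nm


def superpose(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rigid-body fit (Kabsch) of ``mobile`` onto ``reference``.

    Returns ``(R, t, rmsd)`` such that ``x @ R.T + t`` maps mobile points
    onto the reference frame; ``R`` is a proper rotation (det +1).  Requires
    at least three non-collinear points.
    """
    m = np.asarray(mobile, dtype=float)
    r = np.asarray(reference, dtype=float)
    if m.shape != r.shape or m.ndim != 2 or m.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    if m.shape[0] < 3:
        raise ValueError("superposition needs at least 3 points")
    cm = m.mean(axis=0)
    cr = r.mean(axis=0)
    h = (m - cm).T @ (r - cr)
    u, s, vt = np.linalg.svd(h)
    if s[1] <= 1e-12 * max(s[0], 1e-300):
        raise ValueError("points are collinear; superposition is degenerate")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = cr - rot @ cm
    fitted = m @ rot.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - r) ** 2, axis=1))))
    return rot, t, rmsd


@dataclasses.dataclass
class LigationPlan:
    """Index bookkeeping for one peptide-onto-body ligation.

    Fit atoms are 0-based indices into the respective structures and must
    name the same four atoms in the same order.  ``nterm_junction_ca`` /
    ``body_junction_ca`` are the CA of the overlap residue in each
    structure.  ``nterm_span`` is the last residue index counted as
    N-terminus for energy grouping (the flexible span; the cap residue 0 is
    included implicitly).
    """

    nterm_fit_atoms: Sequence[int]
    body_fit_atoms: Sequence[int]
    nterm_junction_ca: int
    body_junction_ca: int
    nterm_span: int

    def __post_init__(self):
        if len(self.nterm_fit_atoms) != 4 or len(self.body_fit_atoms) != 4:
            raise ValueError("fit atom lists must have length 4")


def fit4_indices(structure: Structure, overlap_resid: int | None = None) -> np.ndarray:
    """The four ligation fit atoms of a peptide-like structure.

    C and O of the residue preceding the overlap residue, then N and H of
    the overlap residue (CA when H is absent).  By default the overlap
    residue is the last amino-acid residue (caps ACE/NME excluded).
    """
    chain = structure.chain_ids[0]
    if overlap_resid is None:
        amino = [
            int(r)
            for r, name in structure.sequence(chain)
            if name not in ("ACE", "NME")
        ]
        if len(amino) < 2:
            raise StructureError("need at least two amino residues for fit4")
        overlap_resid = amino[-1]
    prev = overlap_resid - 1
    idx = [
        structure.find_atom(chain, prev, "C"),
        structure.find_atom(chain, prev, "O"),
        structure.find_atom(chain, overlap_resid, "N"),
    ]
    try:
        idx.append(structure.find_atom(chain, overlap_resid, "H"))
    except KeyError:
        idx.append(structure.find_atom(chain, overlap_resid, "CA"))
    return np.asarray(idx, dtype=int)


def make_ligation_plan(
    nterm: Structure, body: Structure, overlap_resid: int, span: int | None = None
) -> LigationPlan:
    """Build the default plan joining ``nterm`` and ``body`` at
    ``overlap_resid`` (1-based, shared numbering)."""
    chain_n = nterm.chain_ids[0]
    chain_b = body.chain_ids[0]
    return LigationPlan(
        nterm_fit_atoms=fit4_indices(nterm, overlap_resid),
        body_fit_atoms=fit4_indices(body, overlap_resid),
        nterm_junction_ca=nterm.find_atom(chain_n, overlap_resid, "CA"),
        body_junction_ca=body.find_atom(chain_b, overlap_resid, "CA"),
        nterm_span=span if span is not None else overlap_resid - 1,
    )


def ligate(nterm: Structure, body: Structure, plan: LigationPlan) -> Structure:
    """Rigid-body fit the peptide onto the body and splice at the junction CA.

    The output contains the peptide's atoms up to and including the junction
    CA followed by the body's atoms after its junction CA; the bond network
    is carried over, with body bonds to its junction CA remapped onto the
    spliced CA.  A post-fit RMSD of the four fit atoms above 0.05 nm
    triggers a warning (the conformer does not present the expected local
    geometry), not an error.
    """
    nf = np.asarray(plan.nterm_fit_atoms, dtype=int)
    bf = np.asarray(plan.body_fit_atoms, dtype=int)
    rot, t, rmsd = superpose(nterm.coords[nf], body.coords[bf])
    if rmsd > FIT_RMSD_WARN:
        warnings.warn(
            f"ligation fit RMSD {rmsd:.3f} nm exceeds {FIT_RMSD_WARN} nm",
            stacklevel=2,
        )
    moved = nterm.coords @ rot.T + t

    jn = plan.nterm_junction_ca
    jb = plan.body_junction_ca
    keep_n = np.arange(jn + 1)
    keep_b = np.arange(jb + 1, body.n_atoms)
    new_index_n = {int(i): k for k, i in enumerate(keep_n)}
    off = len(keep_n)
    new_index_b = {int(i): off + k for k, i in enumerate(keep_b)}
    junction_out = new_index_n[jn]

    bonds = set()
    for i, j in nterm.bonds:
        if i in new_index_n and j in new_index_n:
            bonds.add((new_index_n[i], new_index_n[j]))
    for i, j in body.bonds:
        a = new_index_b.get(i, junction_out if i == jb else None)
        b = new_index_b.get(j, junction_out if j == jb else None)
        if a is not None and b is not None:
            bonds.add((min(a, b), max(a, b)))

    coords = np.vstack([moved[keep_n], body.coords[keep_b]])
    return Structure(
        atom_names=np.concatenate([nterm.atom_names[keep_n], body.atom_names[keep_b]]),
        residue_indices=np.concatenate(
            [nterm.residue_indices[keep_n], body.residue_indices[keep_b]]
        ),
        residue_names=np.concatenate(
            [nterm.residue_names[keep_n], body.residue_names[keep_b]]
        ),
        chain_ids=np.concatenate([nterm.chain_ids[keep_n], body.chain_ids[keep_b]]),
        coords=coords,
        elements=np.concatenate([nterm.elements[keep_n], body.elements[keep_b]]),
        charges=np.concatenate([nterm.charges[keep_n], body.charges[keep_b]]),
        nb_types=np.concatenate([nterm.nb_types[keep_n], body.nb_types[keep_b]]),
        bonds=bonds,
        label=f"{body.label}+nterm",
    )


def _span_groups(stitched: Structure, span: int):
    nterm = np.nonzero(stitched.residue_indices <= span)[0]
    rest = np.nonzero(stitched.residue_indices > span)[0]
    return nterm, rest


def stitch_ensemble(
    ensemble: Ensemble,
    body: Structure,
    plan: LigationPlan,
    params: ForceFieldParams,
    min_cfg: MinimizerConfig | None = None,
):
    """Ligate, relax and filter every conformer of an ensemble.

    Per frame: ligate onto the body, relax with only the reattached
    N-terminal atoms mobile (at most 100 steps, 0.5 kJ/mol tolerance by
    default), evaluate the N-terminus/body cross nonbonded energy, and
    retain the frame iff that energy is strictly negative.  Frames whose
    minimization produces a non-finite energy are dropped and noted in the
    energy table.

    Returns ``(stitched Ensemble of retained frames, energy table, retained
    frame ids)``; the energy table is a list of dicts with keys
    ``frame_id, energy, retained, n_min_steps``.
    """
    min_cfg = min_cfg or MinimizerConfig()
    frames_out: list[np.ndarray] = []
    prov_out: list[dict] = []
    table: list[dict] = []
    topology: Structure | None = None
    model: EnergyModel | None = None
    mobile = None
    groups = None
    for fid in range(len(ensemble)):
        nterm = ensemble.structure(fid)
        stitched = ligate(nterm, body, plan)
        if topology is None:
            topology = stitched
            # mobile: every peptide-contributed atom before the junction CA
            mobile = np.arange(plan.nterm_junction_ca)
            groups = _span_groups(stitched, plan.nterm_span)
            model = EnergyModel(stitched, params, mobile)
        try:
            relaxed, n_steps, _ = steepest_descent(
                stitched, mobile, params, min_cfg, model=model
            )
            energy = nonbonded_energy(relaxed, groups[0], groups[1], params)
        except FloatingPointError:
            table.append(
                {"frame_id": fid, "energy": float("nan"), "retained": False,
                 "n_min_steps": 0}
            )
            continue
        retained = energy < 0.0
        table.append(
            {"frame_id": fid, "energy": float(energy), "retained": bool(retained),
             "n_min_steps": int(n_steps)}
        )
        if retained:
            frames_out.append(relaxed.coords)
            prov = dict(ensemble.provenance[fid])
            prov["source_frame"] = fid
            prov_out.append(prov)
    retained_ids = energy_filter(
        [(row["frame_id"], row["energy"]) for row in table
         if np.isfinite(row["energy"])]
    )
    assert topology is not None
    out = Ensemble(topology, frames_out, prov_out)
    return out, table, retained_ids
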