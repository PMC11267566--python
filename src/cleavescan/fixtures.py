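"""Synthetic structures: ideal-geometry peptides, a rigid protein body
stub, and toy grooved receptors with a bound 9-residue template peptide.

Everything the pipeline consumes can be generated here, deterministically
per seed, with no external structure files.  Geometry uses
literature-standard ideal internal coordinates (bond lengths/angles below)
in the united-atom picture of the bundled force field: backbone N, H, CA,
C, O plus a single side-chain bead CB for every residue except glycine.
Chains are capped with ACE (CH3, C, O; residue 0) and NME (N, H, CH3)
groups so the termini carry complete peptide-bond frames for ligation and
grafting.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .structio import Structure
from .ffenergy import apply_charges, default_forcefield
from .stitcher import LigationPlan, make_ligation_plan
from .grafter import ActiveSiteTemplate

# ideal internal coordinates (nm / degrees)
B_N_H = 0.100
B_N_CA = 0.147
B_CA_C = 0.153
B_C_O = 0.123
B_C_N = 0.133
B_CA_CB = 0.153
B_C_CH3 = 0.152  # ACE methyl-carbonyl
A_N_CA_C = 111.0
A_CA_C_N = 116.0
A_C_N_CA = 122.0
A_CA_C_O = 121.0
A_C_N_H = 119.0
A_CA_N_H = 118.0
A_N_CA_CB = 110.5
OMEGA = 180.0

EXTENDED = (-120.0, 120.0)
HELICAL = (-57.0, -47.0)
BODY_HELIX = HELICAL

AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclasses.dataclass
class FixtureSpec:
    """Parameters of one synthetic study system.

    ``peptide_sequence`` is the sampled N-terminal stretch: the flexible
    span plus one overlap residue shared with the body, hence at least
    five residues.  ``groove`` selects the open channel receptor or the
    variant with a steric obstruction filling the primed subsites.
    """

    peptide_sequence: str = "AVSTLS"
    body_size: int = 30  # residues, including the flexible span
    groove: str = "open"  # "open" | "blocked"
    groove_width: float = 1.2  # nm
    seed: int = 0

    def __post_init__(self):
        if len(self.peptide_sequence) < 5:
            raise ValueError(
                "peptide needs the 4-residue minimum span plus the overlap "
                "residue (>= 5 residues)"
            )
        if self.groove not in ("open", "blocked"):
            raise ValueError("groove must be 'open' or 'blocked'")
        if self.body_size < len(self.peptide_sequence) + 4:
            raise ValueError("body must extend well beyond the flexible span")

    @property
    def span(self) -> int:
        return len(self.peptide_sequence) - 1


# -- internal-coordinate construction ----------------------------------------


def _place(p3, p2, p1, bond, angle_deg, torsion_deg):
    """NeRF placement: new atom bonded to p1 with angle(p2,p1,new) and
    dihedral(p3,p2,p1,new)."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = p1 - p2
    bc = bc / np.linalg.norm(bc)
    n = np.cross(p2 - p3, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [-bond * math.cos(ang),
         bond * math.sin(ang) * math.cos(tor),
         bond * math.sin(ang) * math.sin(tor)]
    )
    return p1 + d[0] * bc + d[1] * m + d[2] * n


def build_chain(
    sequence: str,
    phi: np.ndarray,
    psi: np.ndarray,
    capped: bool = True,
    chain_id: str = "A",
    label: str = "peptide",
) -> Structure:
    """Assemble a peptide from per-residue backbone torsions.

    The chain runs roughly along +x from the origin.  Glycine gets no CB
    bead; every amide nitrogen carries its hydrogen.  Charges come from the
    bundled parameter table.
    """
    seq = sequence.upper()
    if any(c not in AA3 for c in seq):
        bad = sorted(set(c for c in seq if c not in AA3))
        raise ValueError(f"unknown residue code(s): {bad}")
    n_res = len(seq)
    phi = np.broadcast_to(np.asarray(phi, float), (n_res,))
    psi = np.broadcast_to(np.asarray(psi, float), (n_res,))

    pos: dict[tuple[int, str], np.ndarray] = {}
    if capped:
        # ACE cap acts as residue 0 with CH3 in the CA role
        pos[(0, "CH3")] = np.array([0.0, 0.0, 0.0])
        pos[(0, "C")] = np.array([B_C_CH3, 0.0, 0.0])
        pos[(0, "O")] = _place(
            np.array([0.0, 0.0, 1.0]), pos[(0, "CH3")], pos[(0, "C")],
            B_C_O, A_CA_C_O, 90.0,
        )
        prev_ca, prev_c, prev_o = pos[(0, "CH3")], pos[(0, "C")], pos[(0, "O")]
        prev_n = None
    else:
        prev_ca = prev_c = prev_o = prev_n = None

    for i in range(1, n_res + 1):
        if prev_c is not None:
            # N from the previous carbonyl frame; torsion keeps it anti to O
            pos[(i, "N")] = _place(prev_o, prev_ca, prev_c, B_C_N, A_CA_C_N, 180.0)
            pos[(i, "CA")] = _place(prev_ca, prev_c, pos[(i, "N")],
                                    B_N_CA, A_C_N_CA, OMEGA)
            pos[(i, "H")] = _place(prev_ca, prev_c, pos[(i, "N")],
                                   B_N_H, A_C_N_H, 0.0)
            pos[(i, "C")] = _place(prev_c, pos[(i, "N")], pos[(i, "CA")],
                                   B_CA_C, A_N_CA_C, phi[i - 1])
        else:
            pos[(i, "N")] = np.array([0.0, 0.0, 0.0])
            pos[(i, "CA")] = np.array([B_N_CA, 0.0, 0.0])
            pos[(i, "C")] = _place(
                np.array([0.0, 0.0, 1.0]), pos[(i, "N")], pos[(i, "CA")],
                B_CA_C, A_N_CA_C, 60.0,
            )
            pos[(i, "H")] = _place(pos[(i, "C")], pos[(i, "CA")], pos[(i, "N")],
                                   B_N_H, A_CA_N_H, 180.0)
        if seq[i - 1] != "G":
            pos[(i, "CB")] = _place(pos[(i, "C")], pos[(i, "N")], pos[(i, "CA")],
                                    B_CA_CB, A_N_CA_CB, -122.6)
        # O anti to the next amide nitrogen: torsion psi + 180
        pos[(i, "O")] = _place(pos[(i, "N")], pos[(i, "CA")], pos[(i, "C")],
                               B_C_O, A_CA_C_O, psi[i - 1] + 180.0)
        prev_n, prev_ca, prev_c, prev_o = (
            pos[(i, "N")], pos[(i, "CA")], pos[(i, "C")], pos[(i, "O")])

    if capped:
        nme = n_res + 1
        pos[(nme, "N")] = _place(prev_o, prev_ca, prev_c, B_C_N, A_CA_C_N, 180.0)
        pos[(nme, "CH3")] = _place(prev_ca, prev_c, pos[(nme, "N")],
                                   B_N_CA, A_C_N_CA, OMEGA)
        pos[(nme, "H")] = _place(prev_ca, prev_c, pos[(nme, "N")],
                                 B_N_H, A_C_N_H, 0.0)

    # canonical atom order + bonds
    names, resids, resnames, coords = [], [], [], []
    index: dict[tuple[int, str], int] = {}

    def emit(resid, resname, atom_names):
        for a in atom_names:
            index[(resid, a)] = len(names)
            names.append(a)
            resids.append(resid)
            resnames.append(resname)
            coords.append(pos[(resid, a)])

    if capped:
        emit(0, "ACE", ["CH3", "C", "O"])
    for i in range(1, n_res + 1):
        order = ["N", "H", "CA"] + (["CB"] if seq[i - 1] != "G" else []) + ["C", "O"]
        emit(i, AA3[seq[i - 1]], order)
    if capped:
        emit(n_res + 1, "NME", ["N", "H", "CH3"])

    bonds = set()

    def bond(r1, a1, r2, a2):
        bonds.add((index[(r1, a1)], index[(r2, a2)]))

    if capped:
        bond(0, "CH3", 0, "C")
        bond(0, "C", 0, "O")
        bond(0, "C", 1, "N")
    for i in range(1, n_res + 1):
        bond(i, "N", i, "H")
        bond(i, "N", i, "CA")
        if seq[i - 1] != "G":
            bond(i, "CA", i, "CB")
        bond(i, "CA", i, "C")
        bond(i, "C", i, "O")
        if i < n_res:
            bond(i, "C", i + 1, "N")
    if capped:
        bond(n_res, "C", n_res + 1, "N")
        bond(n_res + 1, "N", n_res + 1, "H")
        bond(n_res + 1, "N", n_res + 1, "CH3")

    s = Structure(
        atom_names=names,
        residue_indices=resids,
        residue_names=resnames,
        chain_ids=[chain_id] * len(names),
        coords=np.array(coords),
        bonds=bonds,
        label=label,
    )
    return apply_charges(s, default_forcefield())


def make_peptide(
    sequence: str, conformation: str = "extended", capped: bool = True,
    chain_id: str = "A",
) -> Structure:
    """Ideal-geometry peptide in an extended or alpha-helical conformation."""
    if conformation == "extended":
        phi, psi = EXTENDED
    elif conformation == "helical":
        phi, psi = HELICAL
    else:
        raise ValueError("conformation must be 'extended' or 'helical'")
    n = len(sequence)
    return build_chain(
        sequence, np.full(n, phi), np.full(n, psi), capped=capped,
        chain_id=chain_id, label=f"{conformation}-{sequence}",
    )


# -- rigid body stub ----------------------------------------------------------

MIN_NB_DISTANCE = 0.25  # nm, fixture self-clash contract


def _min_nonbonded_distance(s: Structure) -> float:
    """Smallest nonbonded heavy-bead distance.

    Amide hydrogens are ignored: they carry no Lennard-Jones volume in the
    united-atom parameter set (and helix hydrogen bonds legitimately bring
    them within 0.22 nm of carbonyl oxygens), so only beads with steric
    radius count toward the self-clash contract.
    """
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(s.coords))
    n = s.n_atoms
    mask = np.triu(np.ones((n, n), bool), k=1)
    for i, j in s.excluded_pairs():
        mask[i, j] = False
    heavy = s.atom_names != "H"
    mask &= heavy[:, None] & heavy[None, :]
    return float(d[mask].min())


def _fill_sequence(base: str, n: int, rng: np.random.Generator) -> str:
    extra = "".join(rng.choice(list("ASVLTN")) for _ in range(n - len(base)))
    return base + extra


def make_body(
    n_residues: int,
    seed: int = 0,
    flexible_span: int = 5,
    sequence: str | None = None,
) -> Structure:
    """Rigid helix-hairpin body carrying an extended flexible N-terminus.

    Residues 1..span are extended (the native N-terminal conformation the
    stitcher replaces); the remainder folds as two slightly unwound helices
    joined by a short turn.  Per-seed torsion jitter makes bodies distinct
    while a deterministic retry loop guarantees the self-clash contract
    (every nonbonded atom pair farther apart than 0.25 nm).
    """
    rng = np.random.default_rng(np.random.SeedSequence([17, seed]))
    seq = sequence if sequence is not None else _fill_sequence("", n_residues, rng)
    if len(seq) != n_residues:
        raise ValueError("sequence length must equal n_residues")
    span = flexible_span
    if not 0 < span < n_residues - 4:
        raise ValueError("flexible span must leave a foldable body")
    for attempt in range(25):
        phi = np.empty(n_residues)
        psi = np.empty(n_residues)
        phi[:span], psi[:span] = EXTENDED
        fold = n_residues - span
        h1 = span + (fold - 4) // 2
        turn_phi_psi = [(-76.3, 87.7), (-131.3, 34.7), (-145.3, -67.1),
                        (-92.4, 11.2)]
        for i in range(span, n_residues):
            if i < h1:
                phi[i], psi[i] = BODY_HELIX
            elif i < h1 + 4:
                phi[i], psi[i] = turn_phi_psi[i - h1]
            else:
                phi[i], psi[i] = BODY_HELIX
            phi[i] += rng.normal(0.0, 4.0)
            psi[i] += rng.normal(0.0, 4.0)
        body = build_chain(seq, phi, psi, capped=True, chain_id="A",
                           label=f"body-{seed}")
        if _min_nonbonded_distance(body) > MIN_NB_DISTANCE:
            return body
    raise RuntimeError(
        f"could not build a clash-free body for seed {seed} in 25 attempts"
    )


def extract_nterm(body: Structure, span: int) -> Structure:
    """The body's own N-terminal stretch (cap through the overlap residue),
    usable as a self-ligation conformer."""
    keep = np.nonzero(body.residue_indices <= span + 1)[0]
    new_index = {int(i): k for k, i in enumerate(keep)}
    bonds = {
        (new_index[i], new_index[j])
        for i, j in body.bonds
        if i in new_index and j in new_index
    }
    return Structure(
        atom_names=body.atom_names[keep],
        residue_indices=body.residue_indices[keep],
        residue_names=body.residue_names[keep],
        chain_ids=body.chain_ids[keep],
        coords=body.coords[keep].copy(),
        elements=body.elements[keep],
        charges=body.charges[keep],
        nb_types=body.nb_types[keep],
        bonds=bonds,
        label=f"{body.label}-nterm",
    )


def make_poi(spec: FixtureSpec):
    """Body + sampling peptide + ligation plan for one fixture system.

    The body's sequence starts with ``spec.peptide_sequence`` so the
    sampled peptide (flexible span + overlap residue, capped) ligates onto
    it at the overlap residue.
    """
    rng = np.random.default_rng(np.random.SeedSequence([23, spec.seed]))
    seq = _fill_sequence(spec.peptide_sequence, spec.body_size, rng)
    body = make_body(
        spec.body_size, seed=spec.seed, flexible_span=spec.span, sequence=seq
    )
    peptide = make_peptide(spec.peptide_sequence, "extended", capped=True)
    plan = make_ligation_plan(peptide, body, overlap_resid=spec.span + 1,
                              span=spec.span)
    return body, peptide, plan


# -- toy receptor -------------------------------------------------------------


def _orient_along_x(s: Structure, ca_sel: np.ndarray) -> Structure:
    """Rotate/translate so the CA trace runs along +x through the origin."""
    ca = s.coords[ca_sel]
    centre = ca.mean(axis=0)
    u, _, _ = np.linalg.svd((ca - centre).T @ (ca - centre))
    axis = u[:, 0]
    if np.dot(ca[-1] - ca[0], axis) < 0:
        axis = -axis
    # build right-handed frame with x = axis
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    y = np.cross(ref, axis)
    y /= np.linalg.norm(y)
    z = np.cross(axis, y)
    rot = np.vstack([axis, y, z])
    return s.with_coords((s.coords - centre) @ rot.T)


def make_receptor(spec: FixtureSpec) -> ActiveSiteTemplate:
    """Toy grooved receptor around a bound 9-residue template peptide,
    P-labelled P5..P4'.

    The recognition cleft is a surface groove — five rails of attractive
    CH3 beads forming the floor and side walls of a half-open channel of
    ``groove_width`` — that encloses the unprimed subsites and ends just
    past the scissile bond, leaving the primed side at the surface the way
    a substrate's protein body must be.  The "blocked" variant fills the
    primed subsites (S1' through S4') with purely repulsive beads: an
    obstructed S1' channel no substrate conformation can thread.
    """
    pep = make_peptide("AAAAAAAAA", "extended", capped=False, chain_id="T")
    ca_sel = np.nonzero(pep.atom_names == "CA")[0]
    pep = _orient_along_x(pep, ca_sel)
    chain_t = pep.chain_ids[0]

    radius = spec.groove_width / 2.0
    ca = pep.coords[ca_sel]
    x_lo = float(ca[:, 0].min()) - 0.2
    # groove ends at the scissile bond (N of P1')
    x_hi = float(pep.coords[pep.find_atom(chain_t, 6, "N"), 0])
    xs = np.arange(x_lo, x_hi + 1e-9, 0.3)
    # open top: rails at the rim (+-y) and around the floor (-z)
    angles = [0.0, math.pi, 1.25 * math.pi, 1.5 * math.pi, 1.75 * math.pi]

    names, resids, resnames, nb_types, coords = [], [], [], [], []
    resid = 0
    for ang in angles:
        resid += 1
        for k, x in enumerate(xs):
            names.append(f"W{k + 1}")
            resids.append(resid)
            resnames.append("WAL")
            nb_types.append("CH3")
            coords.append([x, radius * math.cos(ang), radius * math.sin(ang)])
    if spec.groove == "blocked":
        n_p1p = pep.find_atom(chain_t, 6, "N")
        x0 = pep.coords[n_p1p, 0] + 0.05
        x1 = float(ca[:, 0].max()) + 0.2
        grid = np.arange(-radius + 0.1, radius - 0.1 + 1e-9, 0.25)
        for x in np.arange(x0, x1 + 1e-9, 0.25):
            resid += 1
            k = 0
            for y in grid:
                for z in grid:
                    if y * y + z * z <= (radius - 0.1) ** 2:
                        k += 1
                        names.append(f"B{k}")
                        resids.append(resid)
                        resnames.append("BLK")
                        nb_types.append("CR")
                        coords.append([x, y, z])

    protease = Structure(
        atom_names=names,
        residue_indices=resids,
        residue_names=resnames,
        chain_ids=["E"] * len(names),
        coords=np.array(coords),
        elements=["C"] * len(names),
        nb_types=nb_types,
        label=f"receptor-{spec.groove}",
    )
    apply_charges(protease, default_forcefield())
    return ActiveSiteTemplate.from_structures(protease, pep)
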