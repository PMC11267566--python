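"""Molecular-mechanics energy terms and the clash-relaxing minimizer.

The potential is deliberately minimal: harmonic bonds and angles, periodic
torsions, and untruncated Lennard-Jones + Coulomb (vacuum, relative
permittivity 1) over atom pairs separated by more than three bonds.  A
small united-atom parameter table is bundled (see ``data/forcefield.txt``);
user tables in the same plain-text grammar are accepted.

Energy conventions: E_bond = k (b - b0)^2, E_angle = k (theta - theta0)^2,
E_torsion = k (1 + cos(m phi - phase)), E_nb = C12/r^12 - C6/r^6
+ f q_i q_j / r with f = 138.935 kJ mol^-1 nm e^-2.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import math
from typing import Iterable, Sequence

import numpy as np

from .structio import Structure

COULOMB_PREFACTOR = 138.935  # kJ mol^-1 nm e^-2
KB = 0.008314462618  # kJ mol^-1 K^-1


class ParameterError(KeyError):
    """A required force-field parameter is missing."""


@dataclasses.dataclass
class ForceFieldParams:
    """Parsed parameter table.

    ``lj`` maps a sorted nonbonded-type pair to (C12, C6); self pairs are
    required, cross pairs default to the geometric combination and may be
    overridden explicitly.  ``charges`` holds per-type default partial
    charges.  Bond/angle/torsion maps are keyed by sorted end types (angles
    by (min(end), centre, max(end)); torsions by the two central types).
    """

    lj: dict
    charges: dict
    bonds: dict
    angles: dict
    torsions: dict
    coulomb_prefactor: float = COULOMB_PREFACTOR

    def lj_pair(self, t1: str, t2: str) -> tuple[float, float]:
        key = tuple(sorted((t1, t2)))
        if key in self.lj:
            return self.lj[key]
        try:
            c12a, c6a = self.lj[(t1, t1)]
            c12b, c6b = self.lj[(t2, t2)]
        except KeyError as exc:
            raise ParameterError(f"no LJ parameters for type {exc.args[0]}") from exc
        pair = (math.sqrt(c12a * c12b), math.sqrt(c6a * c6b))
        self.lj[key] = pair
        return pair

    def bond_param(self, t1: str, t2: str) -> tuple[float, float]:
        key = tuple(sorted((t1, t2)))
        if key not in self.bonds:
            raise ParameterError(f"no bond parameters for type pair {key}")
        return self.bonds[key]

    def angle_param(self, t1: str, t2: str, t3: str) -> tuple[float, float]:
        key = (min(t1, t3), t2, max(t1, t3))
        if key not in self.angles:
            raise ParameterError(f"no angle parameters for type triple {key}")
        return self.angles[key]

    def torsion_param(self, t2: str, t3: str) -> tuple[float, int, float]:
        key = tuple(sorted((t2, t3)))
        if key not in self.torsions:
            raise ParameterError(f"no torsion parameters for central pair {key}")
        return self.torsions[key]


def load_forcefield(path_or_text) -> ForceFieldParams:
    """Parse a parameter table (strict grammar; see the bundled file)."""
    if hasattr(path_or_text, "read"):
        text = path_or_text.read()
    else:
        text = open(path_or_text).read()
    section = None
    lj, charges, bonds, angles, torsions = {}, {}, {}, {}, {}
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            section = line.strip("[]").upper()
            if section not in {"LJ", "CHARGES", "BONDS", "ANGLES", "TORSIONS"}:
                raise ValueError(f"line {ln}: unknown section [{section}]")
            continue
        parts = line.split()
        try:
            if section == "LJ":
                if len(parts) == 3:
                    t, c12, c6 = parts[0], float(parts[1]), float(parts[2])
                    lj[(t, t)] = (c12, c6)
                elif len(parts) == 4:
                    key = tuple(sorted(parts[:2]))
                    lj[key] = (float(parts[2]), float(parts[3]))
                else:
                    raise ValueError("expected 3 or 4 fields")
            elif section == "CHARGES":
                charges[parts[0]] = float(parts[1])
            elif section == "BONDS":
                k, b0 = float(parts[2]), float(parts[3])
                if k < 0 or b0 <= 0:
                    raise ValueError("bond needs k >= 0 and b0 > 0")
                bonds[tuple(sorted(parts[:2]))] = (k, b0)
            elif section == "ANGLES":
                t1, t2, t3 = parts[:3]
                key = (min(t1, t3), t2, max(t1, t3))
                angles[key] = (float(parts[3]), math.radians(float(parts[4])))
            elif section == "TORSIONS":
                torsions[tuple(sorted(parts[:2]))] = (
                    float(parts[2]),
                    int(parts[3]),
                    math.radians(float(parts[4])),
                )
            else:
                raise ValueError("data before any section header")
        except (IndexError, ValueError) as exc:
            raise ValueError(f"forcefield table line {ln}: {exc}") from exc
    for (t1, t2), (c12, c6) in lj.items():
        if c12 < 0 or c6 < 0:
            raise ValueError(f"negative LJ coefficient for {(t1, t2)}")
    return ForceFieldParams(lj, charges, bonds, angles, torsions)


_DEFAULT = None


def default_forcefield() -> ForceFieldParams:
    """The bundled united-atom table (parsed once, then cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        ref = importlib.resources.files("cleavescan") / "data" / "forcefield.txt"
        _DEFAULT = load_forcefield(ref.open())
    return _DEFAULT


def apply_charges(structure: Structure, params: ForceFieldParams) -> Structure:
    """Fill per-atom partial charges from the table's per-type defaults."""
    q = np.array([params.charges.get(t, 0.0) for t in structure.nb_types])
    structure.charges = q
    return structure


@dataclasses.dataclass
class MinimizerConfig:
    max_steps: int = 100
    energy_tol: float = 0.5  # kJ/mol
    initial_step: float = 0.005  # nm, largest single-atom displacement per step
    step_grow: float = 1.2
    step_shrink: float = 0.5
    count_rejected: bool = False
    min_step: float = 1e-8  # nm; below this the line search has stalled

    def __post_init__(self):
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if self.energy_tol <= 0:
            raise ValueError("energy_tol must be > 0")


# -- term enumeration ---------------------------------------------------------


def _bonded_terms(structure: Structure, params: ForceFieldParams):
    """Enumerate bond, angle and torsion index/parameter arrays.

    One proper torsion per central bond whose end atoms both have further
    neighbours; the lowest-index neighbour on each side defines the
    dihedral.
    """
    t = structure.nb_types
    adj = structure.neighbors()
    bonds = sorted(structure.bonds)
    b_idx, b_k, b_b0 = [], [], []
    for i, j in bonds:
        k, b0 = params.bond_param(t[i], t[j])
        b_idx.append((i, j))
        b_k.append(k)
        b_b0.append(b0)
    a_idx, a_k, a_t0 = [], [], []
    for j in range(structure.n_atoms):
        nb = adj[j]
        for x in range(len(nb)):
            for y in range(x + 1, len(nb)):
                i, k = nb[x], nb[y]
                ka, t0 = params.angle_param(t[i], t[j], t[k])
                a_idx.append((i, j, k))
                a_k.append(ka)
                a_t0.append(t0)
    d_idx, d_k, d_m, d_ph = [], [], [], []
    for j, k in bonds:
        ni = [a for a in adj[j] if a != k]
        nl = [a for a in adj[k] if a != j]
        if not ni or not nl:
            continue
        kt, m, ph = params.torsion_param(t[j], t[k])
        d_idx.append((ni[0], j, k, nl[0]))
        d_k.append(kt)
        d_m.append(m)
        d_ph.append(ph)
    return (
        (np.array(b_idx, int).reshape(-1, 2), np.array(b_k), np.array(b_b0)),
        (np.array(a_idx, int).reshape(-1, 3), np.array(a_k), np.array(a_t0)),
        (
            np.array(d_idx, int).reshape(-1, 4),
            np.array(d_k),
            np.array(d_m, int),
            np.array(d_ph),
        ),
    )


def _nb_pair_arrays(structure, params, pairs):
    i, j = pairs[:, 0], pairs[:, 1]
    t = structure.nb_types
    c12 = np.empty(len(pairs))
    c6 = np.empty(len(pairs))
    for k in range(len(pairs)):
        c12[k], c6[k] = params.lj_pair(t[i[k]], t[j[k]])
    qq = structure.charges[i] * structure.charges[j] * params.coulomb_prefactor
    return i, j, c12, c6, qq


class EnergyModel:
    """Precomputed term lists for repeated energy/gradient evaluation.

    ``mobile`` restricts the model to terms involving at least one mobile
    atom; the reported energy is then the mobile-involving subtotal, whose
    gradient with respect to mobile coordinates equals that of the full
    potential (frozen-frozen terms are constant).
    """

    def __init__(self, structure: Structure, params: ForceFieldParams,
                 mobile: Sequence[int] | None = None):
        self.structure = structure
        self.params = params
        n = structure.n_atoms
        if mobile is None:
            mobile = np.arange(n)
        self.mobile = np.asarray(sorted(set(int(m) for m in mobile)), dtype=int)
        if len(self.mobile) == 0:
            raise ValueError("mobile selection is empty")
        is_mobile = np.zeros(n, dtype=bool)
        is_mobile[self.mobile] = True
        self._is_mobile = is_mobile

        (b, a, d) = _bonded_terms(structure, params)
        self.b_idx, self.b_k, self.b_b0 = b
        self.a_idx, self.a_k, self.a_t0 = a
        self.d_idx, self.d_k, self.d_m, self.d_ph = d
        if len(self.b_idx):
            keep = is_mobile[self.b_idx].any(axis=1)
            self.b_idx, self.b_k, self.b_b0 = (
                self.b_idx[keep], self.b_k[keep], self.b_b0[keep])
        if len(self.a_idx):
            keep = is_mobile[self.a_idx].any(axis=1)
            self.a_idx, self.a_k, self.a_t0 = (
                self.a_idx[keep], self.a_k[keep], self.a_t0[keep])
        if len(self.d_idx):
            keep = is_mobile[self.d_idx].any(axis=1)
            self.d_idx, self.d_k, self.d_m, self.d_ph = (
                self.d_idx[keep], self.d_k[keep], self.d_m[keep], self.d_ph[keep])

        iu, ju = np.triu_indices(n, k=1)
        keep = is_mobile[iu] | is_mobile[ju]
        iu, ju = iu[keep], ju[keep]
        excl = structure.excluded_pairs()
        if excl:
            codes = iu.astype(np.int64) * n + ju
            excl_codes = np.fromiter(
                (i * n + j for i, j in excl), dtype=np.int64, count=len(excl)
            )
            keep = ~np.isin(codes, excl_codes)
            iu, ju = iu[keep], ju[keep]
        pairs = np.column_stack([iu, ju])
        self.nb_i, self.nb_j, self.nb_c12, self.nb_c6, self.nb_qq = (
            _nb_pair_arrays(structure, params, pairs)
            if len(pairs)
            else (np.empty(0, int), np.empty(0, int), np.empty(0), np.empty(0),
                  np.empty(0))
        )

    # -- evaluation ----------------------------------------------------------

    def energy(self, coords: np.ndarray) -> float:
        return self._eval(coords, want_grad=False)[0]

    def energy_grad(self, coords: np.ndarray):
        """(energy, gradient) with the gradient rows ordered as ``mobile``."""
        e, g = self._eval(coords, want_grad=True)
        return e, g[self.mobile]

    def _eval(self, x, want_grad):
        n = self.structure.n_atoms
        g = np.zeros((n, 3)) if want_grad else None
        e = 0.0
        if len(self.b_idx):
            i, j = self.b_idx[:, 0], self.b_idx[:, 1]
            d = x[i] - x[j]
            b = np.linalg.norm(d, axis=1)
            db = b - self.b_b0
            e += float(np.sum(self.b_k * db * db))
            if want_grad:
                f = (2.0 * self.b_k * db / b)[:, None] * d
                np.add.at(g, i, f)
                np.add.at(g, j, -f)
        if len(self.a_idx):
            i, j, k = self.a_idx.T
            u = x[i] - x[j]
            v = x[k] - x[j]
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            cos = np.sum(u * v, axis=1) / (nu * nv)
            cos = np.clip(cos, -1.0, 1.0)
            th = np.arccos(cos)
            dth = th - self.a_t0
            e += float(np.sum(self.a_k * dth * dth))
            if want_grad:
                sin = np.sqrt(np.clip(1.0 - cos * cos, 1e-12, None))
                pref = (2.0 * self.a_k * dth / -sin)
                dcos_du = (v / nv[:, None] - cos[:, None] * u / nu[:, None]) / nu[:, None]
                dcos_dv = (u / nu[:, None] - cos[:, None] * v / nv[:, None]) / nv[:, None]
                gi = pref[:, None] * dcos_du
                gk = pref[:, None] * dcos_dv
                np.add.at(g, i, gi)
                np.add.at(g, k, gk)
                np.add.at(g, j, -(gi + gk))
        if len(self.d_idx):
            i, j, k, l = self.d_idx.T
            b1 = x[j] - x[i]
            b2 = x[k] - x[j]
            b3 = x[l] - x[k]
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            nb2 = np.linalg.norm(b2, axis=1)
            phi = np.arctan2(
                np.sum(np.cross(n1, n2) * b2, axis=1) / nb2,
                np.sum(n1 * n2, axis=1),
            )
            arg = self.d_m * phi - self.d_ph
            e += float(np.sum(self.d_k * (1.0 + np.cos(arg))))
            if want_grad:
                dEdphi = -self.d_k * self.d_m * np.sin(arg)
                sq1 = np.sum(n1 * n1, axis=1)
                sq2 = np.sum(n2 * n2, axis=1)
                gi = (-nb2 / sq1)[:, None] * n1
                gl = (nb2 / sq2)[:, None] * n2
                s12 = np.sum(b1 * b2, axis=1) / (nb2 * nb2)
                s32 = np.sum(b3 * b2, axis=1) / (nb2 * nb2)
                gj = (-1.0 - s12)[:, None] * gi + s32[:, None] * gl
                gk_ = -(gi + gj + gl)
                np.add.at(g, i, dEdphi[:, None] * gi)
                np.add.at(g, j, dEdphi[:, None] * gj)
                np.add.at(g, k, dEdphi[:, None] * gk_)
                np.add.at(g, l, dEdphi[:, None] * gl)
        if len(self.nb_i):
            d = x[self.nb_i] - x[self.nb_j]
            r2 = np.sum(d * d, axis=1)
            if np.any(r2 == 0.0):
                raise FloatingPointError("coincident atoms in nonbonded pair")
            inv2 = 1.0 / r2
            inv6 = inv2 * inv2 * inv2
            r = np.sqrt(r2)
            e_lj = self.nb_c12 * inv6 * inv6 - self.nb_c6 * inv6
            e_q = self.nb_qq / r
            e += float(np.sum(e_lj) + np.sum(e_q))
            if want_grad:
                # dE/dr * (1/r) factors
                coef = (
                    -12.0 * self.nb_c12 * inv6 * inv6 * inv2
                    + 6.0 * self.nb_c6 * inv6 * inv2
                    - self.nb_qq / (r2 * r)
                )
                f = coef[:, None] * d
                np.add.at(g, self.nb_i, f)
                np.add.at(g, self.nb_j, -f)
        return e, g


# -- public operations --------------------------------------------------------


def nonbonded_energy(
    structure: Structure,
    group_a: Sequence[int],
    group_b: Sequence[int],
    params: ForceFieldParams,
    respect_exclusions: bool = True,
) -> float:
    """Cross-group Lennard-Jones + Coulomb energy (kJ/mol), no cutoff.

    Pairs within three bonds of each other in the structure's bond graph are
    skipped when ``respect_exclusions`` (atoms covalently linked across a
    group boundary do not count as a nonbonded contact).  Overlapping groups
    or a zero interatomic distance are errors.
    """
    a = np.asarray(group_a, dtype=int)
    b = np.asarray(group_b, dtype=int)
    if len(np.intersect1d(a, b)) > 0:
        raise ValueError("groups overlap")
    ii, jj = np.meshgrid(a, b, indexing="ij")
    i = ii.ravel()
    j = jj.ravel()
    lo, hi = np.minimum(i, j), np.maximum(i, j)
    if respect_exclusions:
        excl = structure.excluded_pairs()
        if excl:
            n = structure.n_atoms
            codes = lo.astype(np.int64) * n + hi
            excl_codes = np.fromiter(
                (p * n + q for p, q in excl), dtype=np.int64, count=len(excl)
            )
            keep = ~np.isin(codes, excl_codes)
            lo, hi = lo[keep], hi[keep]
    if len(lo) == 0:
        return 0.0
    order = np.lexsort((hi, lo))  # canonical order: E(A,B) == E(B,A) exactly
    pairs = np.column_stack([lo[order], hi[order]])
    pi, pj, c12, c6, qq = _nb_pair_arrays(structure, params, pairs)
    d = structure.coords[pi] - structure.coords[pj]
    r2 = np.sum(d * d, axis=1)
    if np.any(r2 == 0.0):
        raise FloatingPointError("zero distance between nonbonded atoms")
    inv6 = (1.0 / r2) ** 3
    return float(np.sum(c12 * inv6 * inv6 - c6 * inv6 + qq / np.sqrt(r2)))


def intra_energy(
    structure: Structure,
    mobile: Sequence[int],
    params: ForceFieldParams,
):
    """Bonded + nonbonded energy of terms involving mobile atoms, and the
    analytic gradient for the mobile atoms (rows ordered as the sorted
    mobile selection)."""
    model = EnergyModel(structure, params, mobile)
    return model.energy_grad(structure.coords)


def steepest_descent(
    structure: Structure,
    mobile: Sequence[int],
    params: ForceFieldParams,
    cfg: MinimizerConfig | None = None,
    model: EnergyModel | None = None,
    trace: list | None = None,
):
    """Steepest-descent relaxation of the mobile atoms.

    The step length caps the largest single-atom displacement; it grows on
    accepted steps and shrinks on rejected ones (rejections do not count
    toward ``max_steps`` unless ``cfg.count_rejected``).  Terminates when an
    accepted step changes the energy by less than ``energy_tol``, after
    ``max_steps`` accepted steps, or when the step length underflows.

    Returns ``(relaxed structure, accepted step count, converged flag)``.
    Only mobile atoms are displaced.  When ``trace`` is a list, the energy
    of every accepted iterate (including the start) is appended to it.
    """
    cfg = cfg or MinimizerConfig()
    if model is None:
        model = EnergyModel(structure, params, mobile)
    x = structure.coords.copy()
    e, g = model.energy_grad(x)
    if not np.isfinite(e):
        raise FloatingPointError("non-finite energy at minimization start")
    if trace is not None:
        trace.append(e)
    step = cfg.initial_step
    n_acc = 0
    converged = False
    guard = 0
    while n_acc < cfg.max_steps:
        guard += 1
        if guard > cfg.max_steps * 64:
            break
        gmax = np.max(np.abs(g))
        if gmax == 0.0:
            converged = True
            break
        trial = x.copy()
        trial[model.mobile] = x[model.mobile] - g * (step / gmax)
        try:
            e_new, g_new = model.energy_grad(trial)
        except FloatingPointError:
            e_new = np.inf
            g_new = None
        if np.isfinite(e_new) and e_new <= e:
            x = trial
            n_acc += 1
            delta = e - e_new
            e, g = e_new, g_new
            if trace is not None:
                trace.append(e)
            step *= cfg.step_grow
            if delta < cfg.energy_tol:
                converged = True
                break
        else:
            step *= cfg.step_shrink
            if cfg.count_rejected:
                n_acc += 1
            if step < cfg.min_step:
                break
    return structure.with_coords(x), n_acc, converged


def energy_filter(items: Iterable[tuple], threshold: float = 0.0) -> list:
    """Ids of items whose energy is strictly below ``threshold``.

    The boundary itself is excluded — an energy of exactly ``threshold``
    (zero by default) is not favorable.  Input order is preserved.
    """
    retained = []
    for item_id, energy in items:
        if not np.isfinite(energy):
            raise ValueError(f"non-finite energy for item {item_id!r}")
        if energy < threshold:
            retained.append(item_id)
    return retained
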