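"""Conformational search of capped N-terminal peptides.

Diversity, not dynamics, is the contract here: downstream stages only
consume a broad set of conformers.  The search is a Metropolis walk in
torsion space (backbone phi/psi rotations at ideal bond lengths and
angles) run hot (600 K by default), with a local-elevation (LE) memory
bias on the end-to-end distance between the peptide's terminal N and C
atoms.  Every production step deposits one penalty increment at the grid
point nearest the current distance; the accumulating repulsive bias pushes
the walk away from already-visited distances, flattening the end-to-end
distance distribution.

The LE grid is parameterised exactly as in GROMOS LEUS input blocks:
GRIDMIN/GRIDMAX (nm), NGRID points (endpoints inclusive), WLES (local
function width, in grid spacings), RLES (truncation radius, in grid
spacings) and CLES (penalty increment per visit, kJ/mol).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structio import Structure, Ensemble
from .ffenergy import EnergyModel, ForceFieldParams, KB

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class LEConfig:
    """Local-elevation grid and bias parameters (GROMOS LEUS naming)."""

    grid_min: float = 0.4  # nm (GRIDMIN)
    grid_max: float = 4.0  # nm (GRIDMAX)
    n_grid: int = 100  # NGRID
    wles: float = 2.0  # local-function width, grid spacings
    rles: float = 2.5  # truncation radius, grid spacings
    cles: float = 2.25e-5  # kJ/mol per visit

    def __post_init__(self):
        if not self.grid_min < self.grid_max:
            raise ValueError("grid_min must be < grid_max")
        if self.n_grid < 2:
            raise ValueError("n_grid must be >= 2")
        if min(self.wles, self.rles, self.cles) <= 0:
            raise ValueError("wles, rles and cles must be > 0")

    @property
    def spacing(self) -> float:
        return (self.grid_max - self.grid_min) / (self.n_grid - 1)


def build_le_grid(cfg: LEConfig) -> np.ndarray:
    """Grid point centres: ``n_grid`` points, endpoints inclusive."""
    return np.linspace(cfg.grid_min, cfg.grid_max, cfg.n_grid)


class LEMemory:
    """Per-grid-point visit counts; the bias is counts x CLES x local fn."""

    def __init__(self, cfg: LEConfig):
        self.cfg = cfg
        self.grid = build_le_grid(cfg)
        self.visit_counts = np.zeros(cfg.n_grid, dtype=np.int64)

    def deposit(self, distance: float) -> int:
        """Record one visit at the grid point nearest ``distance``.

        Ties between two equidistant neighbours go to the lower-index
        point; out-of-range distances clamp to the nearest end point.
        """
        d = float(np.clip(distance, self.cfg.grid_min, self.cfg.grid_max))
        below = int((d - self.cfg.grid_min) // self.cfg.spacing)
        below = min(below, self.cfg.n_grid - 2)
        g = below if (d - self.grid[below]) <= (self.grid[below + 1] - d) else below + 1
        self.visit_counts[g] += 1
        return g


def le_bias(distance: float, memory: LEMemory, cfg: LEConfig) -> float:
    """Accumulated penalty energy at ``distance`` (kJ/mol, >= 0).

    The local function is a Gaussian of width WLES x spacing with a
    quadratic tail correction that brings it continuously to zero at the
    RLES x spacing truncation radius while keeping the value at a visited
    centre exactly visits x CLES.  Distances outside the grid are clamped
    to the nearest grid point (logged once per memory).
    """
    if distance < cfg.grid_min or distance > cfg.grid_max:
        if not getattr(memory, "_clamp_logged", False):
            logger.info("LE distance %.3f nm outside grid; clamping", distance)
            memory._clamp_logged = True
        distance = float(np.clip(distance, cfg.grid_min, cfg.grid_max))
    delta = cfg.spacing
    sigma = cfg.wles * delta
    rcut = cfg.rles * delta
    dx = distance - memory.grid
    within = np.abs(dx) < rcut
    if not np.any(within):
        return 0.0
    x2 = dx[within] ** 2
    edge = np.exp(-(rcut * rcut) / (2.0 * sigma * sigma))
    local = np.exp(-x2 / (2.0 * sigma * sigma)) - edge * x2 / (rcut * rcut)
    local = np.maximum(local, 0.0)
    return float(np.sum(memory.visit_counts[within] * cfg.cles * local))


@dataclasses.dataclass
class EquilStage:
    temperature: float  # K
    restraint_k: float  # kJ mol^-1 nm^-2, 0 = released
    n_steps: int


def default_equilibration(n_steps_per_stage: int = 200) -> list[EquilStage]:
    """Ten-stage heat-up, 60 K per stage to 600 K, positional restraints
    starting at 2.5e4 kJ/mol/nm^2 and weakening tenfold per stage before
    full release."""
    stages = []
    for i in range(10):
        k = 2.5e4 / (10.0**i) if i < 5 else 0.0
        stages.append(EquilStage(60.0 * (i + 1), k, n_steps_per_stage))
    return stages


@dataclasses.dataclass
class SamplerConfig:
    temperature: float = 600.0  # K, production
    n_steps: int = 5000  # production steps per replicate
    n_replicates: int = 10
    seed: int = 0
    save_interval: int = 10  # production steps between saved frames
    torsion_step_deg: float = 30.0  # proposal width
    equilibration: list[EquilStage] | None = None  # None = default ramp
    equilibrate: bool = True
    stall_window: int = 1000  # error if no move accepted in this many steps

    def __post_init__(self):
        if self.equilibration is None:
            self.equilibration = default_equilibration()
        temps = [s.temperature for s in self.equilibration]
        if any(t <= 0 for t in temps) or any(
            b < a for a, b in zip(temps, temps[1:])
        ):
            raise ValueError("equilibration temperatures must be positive and "
                             "non-decreasing")


# -- torsion machinery --------------------------------------------------------


class TorsionMover:
    """Rotatable backbone torsions (phi: N-CA, psi: CA-C) of one peptide.

    Rotating about a bond moves the C-terminal side of the chain rigidly;
    bond lengths and angles are untouched, standing in for constrained
    dynamics.
    """

    def __init__(self, peptide: Structure):
        self.structure = peptide
        adj = peptide.neighbors()
        names = peptide.atom_names
        bonds = []
        for i, j in sorted(peptide.bonds):
            pair = {names[i], names[j]}
            if pair == {"N", "CA"} or pair == {"CA", "C"}:
                if peptide.residue_indices[i] == peptide.residue_indices[j]:
                    bonds.append((i, j))
        self.axes = []
        for i, j in bonds:
            downstream = self._component(adj, j, i)
            if 0 < len(downstream) < peptide.n_atoms - 1:
                self.axes.append((i, j, np.asarray(sorted(downstream), dtype=int)))
        if not self.axes:
            raise ValueError("peptide has no rotatable backbone torsions")

    @staticmethod
    def _component(adj, start, blocked):
        seen = {start, blocked}
        stack = [start]
        comp = {start}
        while stack:
            a = stack.pop()
            for b in adj[a]:
                if b not in seen:
                    seen.add(b)
                    comp.add(b)
                    stack.append(b)
        comp.discard(blocked)
        comp.discard(start)
        return comp

    def rotate(self, coords: np.ndarray, axis_id: int, angle: float) -> np.ndarray:
        i, j, downstream = self.axes[axis_id]
        axis = coords[j] - coords[i]
        norm = np.linalg.norm(axis)
        rot = Rotation.from_rotvec(axis / norm * angle)
        out = coords.copy()
        out[downstream] = rot.apply(coords[downstream] - coords[j]) + coords[j]
        return out


def terminal_atoms(peptide: Structure) -> tuple[int, int]:
    """Indices of the first backbone N and the last carbonyl C — the
    end-to-end distance atoms the LE bias acts on."""
    names = peptide.atom_names
    n_idx = next((i for i in range(peptide.n_atoms) if names[i] == "N"), None)
    c_idx = next(
        (i for i in range(peptide.n_atoms - 1, -1, -1) if names[i] == "C"), None
    )
    if n_idx is None or c_idx is None:
        raise ValueError("peptide lacks terminal N/C atoms")
    return n_idx, c_idx


def sample_conformers(
    peptide: Structure,
    s_cfg: SamplerConfig,
    le_cfg: LEConfig | None,
    params: ForceFieldParams,
) -> Ensemble:
    """Metropolis torsion search with optional LE distance bias.

    Runs ``n_replicates`` independent walks (per-replicate seeds spawned
    deterministically from ``s_cfg.seed``), each with the equilibration
    temperature/restraint ramp followed by ``n_steps`` production steps at
    ``temperature``; frames are recorded every ``save_interval`` production
    steps.  ``le_cfg=None`` disables the bias (all else equal).
    """
    mover = TorsionMover(peptide)
    model = EnergyModel(peptide, params)
    n_end, c_end = terminal_atoms(peptide)
    x0 = peptide.coords.copy()

    frames: list[np.ndarray] = []
    prov: list[dict] = []
    seeds = np.random.SeedSequence(s_cfg.seed).spawn(s_cfg.n_replicates)
    for rep, seed_seq in enumerate(seeds):
        rng = np.random.default_rng(seed_seq)
        memory = LEMemory(le_cfg) if le_cfg is not None else None
        x = x0.copy()
        e = model.energy(x)

        def total(coords, e_intra, restraint_k):
            out = e_intra
            if restraint_k > 0.0:
                out += restraint_k * float(np.sum((coords - x0) ** 2))
            if memory is not None and stage_is_production:
                d = float(np.linalg.norm(coords[c_end] - coords[n_end]))
                out += le_bias(d, memory, le_cfg)
            return out

        stage_is_production = False
        schedule: list[tuple[float, float, int, bool]] = []
        if s_cfg.equilibrate:
            for st in s_cfg.equilibration:
                schedule.append((st.temperature, st.restraint_k, st.n_steps, False))
        schedule.append((s_cfg.temperature, 0.0, s_cfg.n_steps, True))

        for temp, res_k, n_steps, production in schedule:
            stage_is_production = production
            beta = 1.0 / (KB * temp)
            e_tot = total(x, e, res_k)
            since_accept = 0
            for step in range(n_steps):
                axis_id = int(rng.integers(len(mover.axes)))
                angle = rng.normal(0.0, np.radians(s_cfg.torsion_step_deg))
                trial = mover.rotate(x, axis_id, angle)
                e_trial = model.energy(trial)
                e_tot_trial = total(trial, e_trial, res_k)
                accept = e_tot_trial <= e_tot or rng.random() < np.exp(
                    -beta * (e_tot_trial - e_tot)
                )
                if accept:
                    x, e, e_tot = trial, e_trial, e_tot_trial
                    since_accept = 0
                else:
                    since_accept += 1
                    if since_accept >= s_cfg.stall_window:
                        raise RuntimeError(
                            "no accepted moves in "
                            f"{s_cfg.stall_window} steps; review temperature "
                            "or torsion_step_deg"
                        )
                if production:
                    if memory is not None:
                        d = float(np.linalg.norm(x[c_end] - x[n_end]))
                        memory.deposit(d)
                        # bias grew under our feet; refresh the reference total
                        e_tot = total(x, e, res_k)
                    if (step + 1) % s_cfg.save_interval == 0:
                        frames.append(x.copy())
                        prov.append(
                            {"replicate": rep, "step": step + 1,
                             "seed": int(s_cfg.seed)}
                        )
    return Ensemble(peptide, frames, prov)


def random_frame_selection(
    ensembles: Sequence[Ensemble] | Ensemble, n: int = 10000, seed: int = 0
) -> Ensemble:
    """Uniform selection without replacement across the pooled frames.

    Takes the whole pool (with a log message) when it holds fewer than
    ``n`` frames.  Provenance is carried along; the selection is
    deterministic for a fixed seed.
    """
    if isinstance(ensembles, Ensemble):
        ensembles = [ensembles]
    topology = ensembles[0].topology
    pool_frames: list[np.ndarray] = []
    pool_prov: list[dict] = []
    for ens in ensembles:
        if ens.topology.n_atoms != topology.n_atoms:
            raise ValueError("ensembles do not share a topology")
        pool_frames.extend(ens.frames)
        pool_prov.extend(ens.provenance)
    total = len(pool_frames)
    if total <= n:
        if total < n:
            logger.warning("pool has %d < %d frames; taking all", total, n)
        return Ensemble(topology, list(pool_frames), list(pool_prov))
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(total, size=n, replace=False))
    return Ensemble(
        topology,
        [pool_frames[i] for i in chosen],
        [dict(pool_prov[i], pool_index=int(i)) for i in chosen],
    )
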