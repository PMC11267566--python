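"""One-command orchestration of the cleavability workflow.

The stages mirror the method's eight steps: identify the flexible
N-terminus, sample its conformations (hot torsion search + LE bias),
select a random subset, stitch the conformers back onto the rigid body,
relax and filter, optionally cluster to representative structures, graft
into the protease active site, relax and filter again, and score the
fraction of fitting conformers.  Every stage's parameters, seeds and
output hashes go into a machine-readable manifest so a run can be
reproduced bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fixtures
from .structio import (
    Ensemble,
    determine_flexible_span,
    read_bond_list,
    read_pdb,
    write_pdb,
)
from .ffenergy import (
    MinimizerConfig,
    apply_charges,
    default_forcefield,
    load_forcefield,
)
from .lesampler import (
    LEConfig,
    SamplerConfig,
    random_frame_selection,
    sample_conformers,
)
from .stitcher import make_ligation_plan, stitch_ensemble
from .clusterer import central_members, cutoff_for_target_k, daura_cluster, rmsd_matrix
from .grafter import ActiveSiteTemplate, fit_ensemble
from .fixtures import FixtureSpec, make_peptide, make_poi, make_receptor
from .report import CleavabilityReport, cleavability_score, write_report

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class EmptyRetentionError(RuntimeError):
    """No conformers survived a retention filter — a valid empty result,
    distinct from a stage failure."""


@dataclasses.dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Inputs come either from files (``poi_pdb`` + ``poi_bonds`` +
    ``template``...) or from the synthetic fixture generator
    (``fixture``); exactly one of the two must be given.  LE keys reuse
    the GROMOS names (gridmin/gridmax/ngrid/wles/rles/cles) for
    traceability.
    """

    # file inputs
    poi_pdb: str | None = None
    poi_bonds: str | None = None
    secondary_structure: str | None = None  # per-residue H/E/C
    template: str | dict | None = None  # active-site template config (YAML)
    forcefield: str | None = None  # None = bundled table
    # synthetic inputs
    fixture: FixtureSpec | None = None
    # span override (residue count); None = derive
    flexible_span: int | None = None
    # sampler / LE
    sampler: SamplerConfig = dataclasses.field(
        default_factory=lambda: SamplerConfig(n_replicates=3, n_steps=2000)
    )
    le: LEConfig | None = dataclasses.field(
        default_factory=lambda: LEConfig(grid_min=0.3, grid_max=2.6, n_grid=40,
                                         cles=0.5)
    )
    # selection / clustering / scoring
    n_select: int = 10000
    target_k: int = 100
    mode: str = "complete"  # "complete" | "clustered"
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if self.mode not in ("complete", "clustered"):
            raise ConfigError("mode must be 'complete' or 'clustered'")


def config_from_yaml(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kw = {}
    for key in ("poi_pdb", "poi_bonds", "secondary_structure", "template",
                "forcefield", "flexible_span", "n_select", "target_k", "mode",
                "seed", "out_dir"):
        if key in raw:
            kw[key] = raw[key]
    if "fixture" in raw:
        kw["fixture"] = FixtureSpec(**raw["fixture"])
    if "sampler" in raw:
        kw["sampler"] = SamplerConfig(**raw["sampler"])
    if "le" in raw:
        le = raw["le"]
        if le is None:
            kw["le"] = None
        else:
            kw["le"] = LEConfig(
                grid_min=le.get("gridmin", 0.4),
                grid_max=le.get("gridmax", 4.0),
                n_grid=le.get("ngrid", 100),
                wles=le.get("wles", 2.0),
                rles=le.get("rles", 2.5),
                cles=le.get("cles", 2.25e-5),
            )
    return RunConfig(**kw)


def validate_config(cfg: RunConfig) -> list[str]:
    """Schema and cross-field checks; an empty list means the config is
    runnable."""
    issues: list[str] = []
    if (cfg.fixture is None) == (cfg.poi_pdb is None):
        issues.append("exactly one of 'fixture' or 'poi_pdb' must be set")
    for attr in ("poi_pdb", "poi_bonds", "forcefield"):
        p = getattr(cfg, attr)
        if p is not None and not Path(p).exists():
            issues.append(f"{attr} path does not exist: {p}")
    if cfg.poi_pdb is not None and cfg.secondary_structure is None and \
            cfg.flexible_span is None:
        issues.append("file input needs secondary_structure or flexible_span")
    if cfg.poi_pdb is not None and cfg.template is None:
        issues.append("file input needs an active-site template config")
    if cfg.le is not None:
        try:
            LEConfig(cfg.le.grid_min, cfg.le.grid_max, cfg.le.n_grid,
                     cfg.le.wles, cfg.le.rles, cfg.le.cles)
        except ValueError as exc:
            issues.append(f"le: {exc}")
    if cfg.n_select < 1:
        issues.append("n_select must be >= 1")
    if cfg.target_k < 1:
        issues.append("target_k must be >= 1")
    return issues


def template_from_config(source, params) -> ActiveSiteTemplate:
    """Load an active-site template from a YAML config (or a dict).

    Keys: ``pdb`` (structure file holding protease and bound peptide),
    ``bonds`` (optional sidecar), ``peptide_chain`` (chain id of the
    9-residue template peptide; all other chains form the protease).
    Residues are labelled P5..P4' in residue order.
    """
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text())
    else:
        raw = dict(source)
    structure = read_pdb(raw["pdb"], bonds_path=raw.get("bonds"))
    if isinstance(structure, Ensemble):
        structure = structure.structure(0)
    apply_charges(structure, params)
    chain = str(raw["peptide_chain"])
    pep_idx = np.nonzero(structure.chain_ids == chain)[0]
    prot_idx = np.nonzero(structure.chain_ids != chain)[0]
    if len(pep_idx) == 0:
        raise ConfigError(f"template: no atoms on peptide chain {chain!r}")

    def _subset(keep):
        new_index = {int(i): k for k, i in enumerate(keep)}
        bonds = {
            (new_index[i], new_index[j])
            for i, j in structure.bonds
            if i in new_index and j in new_index
        }
        return type(structure)(
            atom_names=structure.atom_names[keep],
            residue_indices=structure.residue_indices[keep],
            residue_names=structure.residue_names[keep],
            chain_ids=structure.chain_ids[keep],
            coords=structure.coords[keep].copy(),
            elements=structure.elements[keep],
            charges=structure.charges[keep],
            nb_types=structure.nb_types[keep],
            bonds=bonds,
            label=structure.label,
        )

    return ActiveSiteTemplate.from_structures(_subset(prot_idx), _subset(pep_idx))


def _hash_array(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:16]


def _hash_frames(ens: Ensemble) -> str:
    h = hashlib.sha256()
    for f in ens.frames:
        h.update(np.ascontiguousarray(f).tobytes())
    return h.hexdigest()[:16]


def run_all(cfg: RunConfig) -> CleavabilityReport:
    """Execute the full pipeline; artifacts land in ``cfg.out_dir`` if set.

    Stage seeds derive deterministically from ``cfg.seed``; two runs with
    an identical config produce byte-identical reports and manifests.  A
    stage failure raises :class:`StageError` naming the stage, leaving
    earlier artifacts in place.
    """
    issues = validate_config(cfg)
    if issues:
        raise ConfigError("; ".join(issues))
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "seed": cfg.seed, "mode": cfg.mode}

    def record(stage: str, **info):
        manifest["stages"].append(dict(stage=stage, **info))
        logger.info("stage %s: %s", stage, info)

    params = (
        load_forcefield(cfg.forcefield) if cfg.forcefield else default_forcefield()
    )

    # -- stage 1: inputs and flexible span
    try:
        if cfg.fixture is not None:
            fixture = dataclasses.replace(cfg.fixture)
            body, peptide, plan = make_poi(fixture)
            template = make_receptor(fixture)
            span = fixture.span
        else:
            structure = read_pdb(cfg.poi_pdb, bonds_path=cfg.poi_bonds)
            if isinstance(structure, Ensemble):
                structure = structure.structure(0)
            apply_charges(structure, params)
            span = cfg.flexible_span or determine_flexible_span(
                cfg.secondary_structure
            )
            seq = "".join(
                next(k for k, v in fixtures.AA3.items() if v == name)
                for rid, name in structure.sequence(structure.chain_ids[0])
                if name not in ("ACE", "NME") and rid <= span + 1
            )
            body = structure
            peptide = make_peptide(seq, "extended", capped=True)
            plan = make_ligation_plan(peptide, body, overlap_resid=span + 1,
                                      span=span)
            template = template_from_config(cfg.template, params)
        record("inputs", span=span, body_atoms=body.n_atoms,
               body_hash=_hash_array(body.coords))
    except (ConfigError,):
        raise
    except Exception as exc:
        raise StageError("inputs", exc) from exc

    sampler_cfg = dataclasses.replace(cfg.sampler, seed=cfg.seed)

    def stage(fn, name):
        try:
            return fn()
        except Exception as exc:
            if out_dir:
                (out_dir / "manifest.json").write_text(
                    json.dumps(manifest, indent=2, sort_keys=True) + "\n"
                )
            raise StageError(name, exc) from exc

    # -- stage 2: conformational sampling
    def _sample():
        ens = sample_conformers(peptide, sampler_cfg, cfg.le, params)
        record("sample", n_frames=len(ens), frames_hash=_hash_frames(ens),
               seed=sampler_cfg.seed)
        return ens

    ensemble = stage(_sample, "sample")

    # -- stage 3: random selection
    def _select():
        sel = random_frame_selection(ensemble, n=cfg.n_select,
                                     seed=cfg.seed + 1)
        record("select", n_selected=len(sel), frames_hash=_hash_frames(sel))
        return sel

    selected = stage(_select, "select")
    if out_dir:
        write_pdb(selected, out_dir / "ensemble.pdb")

    # -- stage 4: stitch + relax + filter
    def _stitch():
        stitched, table, retained = stitch_ensemble(
            selected, body, plan, params, MinimizerConfig()
        )
        record("stitch", n_in=len(selected), n_retained=len(retained),
               frames_hash=_hash_frames(stitched))
        return stitched, table, retained

    stitched, stitch_table, stitch_retained = stage(_stitch, "stitch")
    if out_dir:
        pd.DataFrame(stitch_table).to_csv(
            out_dir / "stitch_energies.tsv", sep="\t", index=False
        )
        write_pdb(stitched, out_dir / "stitched.pdb")
    if len(stitched) == 0:
        raise EmptyRetentionError("no conformers retained after stitching")

    # -- stage 5: optional clustering
    if cfg.mode == "clustered" and len(stitched) > 1:
        def _cluster():
            matrix = rmsd_matrix(
                stitched,
                align_sel=f"name N CA C and resid {span + 2}-100000",
                rmsd_sel=f"name N CA C and resid 1-{span}",
            )
            cutoff, achieved = cutoff_for_target_k(matrix, cfg.target_k)
            clustering = daura_cluster(matrix, cutoff)
            reps = central_members(clustering, stitched)
            record("cluster", cutoff=round(cutoff, 4), n_clusters=achieved,
                   frames_hash=_hash_frames(reps))
            return reps, clustering

        conformers, clustering = stage(_cluster, "cluster")
        if out_dir:
            rows = [
                {"frame_id": m, "cluster_id": cid, "is_center": int(m == c)}
                for cid, (c, members) in enumerate(clustering.clusters)
                for m in members
            ]
            pd.DataFrame(rows).to_csv(out_dir / "clusters.tsv", sep="\t",
                                      index=False)
    else:
        conformers = stitched

    # -- stages 6-7: graft + relax + filter
    def _graft():
        outcomes = fit_ensemble(conformers, template, params,
                                MinimizerConfig(), nterm_span=span)
        record("graft", n_in=len(conformers),
               n_retained=sum(o.retained for o in outcomes))
        return outcomes

    outcomes = stage(_graft, "graft")
    if out_dir:
        pd.DataFrame([dataclasses.asdict(o) for o in outcomes]).to_csv(
            out_dir / "outcomes.tsv", sep="\t", index=False
        )

    # -- stage 8: score
    rep = cleavability_score(outcomes, mode=cfg.mode)
    record("score", n_total=rep.n_total, n_retained=rep.n_retained,
           fraction=rep.fraction_fitted)
    if out_dir:
        write_report(rep, out_dir / "report.json")
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    return rep
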