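"""End-to-end orchestration: cohort -> mirroring -> 16 segments -> ICP ->
correspondence -> per-segment shape models -> variation tables.

The pipeline consumes either a synthetic population specification or a
directory of STL/PLY canal surfaces (already axis-aligned in the shared
frame, distal end toward low z). Per-subject failures skip the subject with a
logged reason; per-stage failures halt with a stage-labelled error.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correspondence import CorrespondedMesh, rbf_register
from .errors import CanalSSMError, ParameterError
from .features import DEFAULT_SPACING_MM
from .mesh import TriMesh, read_mesh
from .metrics import NEGLIGIBLE_PCT, VariationTable, variation_table
from .preprocess import (DEFAULT_ICP_TOL_ROT_DEG, DEFAULT_ICP_TOL_TRANS_MM,
                         SEGMENT_FRACTIONS, choose_reference, cut_segment,
                         icp_align, mirror_canal)
from .ssm import DEFAULT_N_PCS, SSMModel, build_ssm, explained_variance, n_modes_for
from .synthetic import Cohort, PopulationSpec, generate_population

log = logging.getLogger(__name__)

_DEGENERATE_VAR_MM2 = 1e-10


@dataclass
class PipelineConfig:
    """Everything a full run needs; defaults follow the analysis conventions
    used throughout the package (10 mm slices, 0.01 mm / 0.05° ICP stopping,
    0.001 mm / 50-iteration elastic registration, 4 reported PCs, 90%
    variance threshold, 5% negligibility)."""

    population: PopulationSpec | None = None
    input_dir: str | None = None
    fractions: tuple = SEGMENT_FRACTIONS
    spacing_mm: float = DEFAULT_SPACING_MM
    icp_tol_trans_mm: float = DEFAULT_ICP_TOL_TRANS_MM
    icp_tol_rot_deg: float = DEFAULT_ICP_TOL_ROT_DEG
    icp_max_iter: int = 200
    rbf_tol_mm: float = 0.001
    rbf_max_iter: int = 50
    rbf_controls: int = 200
    n_pcs: int = DEFAULT_N_PCS
    variance_threshold: float = 0.90
    negligible_pct: float = NEGLIGIBLE_PCT
    outdir: str | None = None

    def __post_init__(self):
        if (self.population is None) == (self.input_dir is None):
            raise ParameterError(
                "config must name exactly one input: a PopulationSpec or a mesh directory")


@dataclass
class FractionResult:
    """Everything computed for one segment fraction."""

    fraction: float
    model: SSMModel
    variance_fractions: np.ndarray
    cumulative_variance: np.ndarray
    n_modes_90: int
    variation: VariationTable | None
    degenerate: bool
    icp_log: pd.DataFrame
    rbf_log: pd.DataFrame


@dataclass
class PipelineResult:
    """Bundle of all per-fraction results plus cohort-level bookkeeping."""

    config: PipelineConfig
    reference_index: int
    sides: list[str]
    fractions: dict = field(default_factory=dict)   # fraction -> FractionResult
    cohort: Cohort | None = None

    def variance_summary(self) -> pd.DataFrame:
        rows = []
        for f, fr in sorted(self.fractions.items()):
            row = {"fraction": f, "n_modes_90": fr.n_modes_90,
                   "degenerate": fr.degenerate}
            for i, v in enumerate(fr.variance_fractions[:8], start=1):
                row[f"pc{i}_pct"] = 100.0 * v
            rows.append(row)
        return pd.DataFrame(rows)


def _load_meshes(config: PipelineConfig) -> tuple[list[TriMesh], Cohort | None]:
    if config.population is not None:
        cohort = generate_population(config.population)
        return cohort.meshes, cohort
    paths = sorted(p for p in os.listdir(config.input_dir)
                   if p.lower().endswith((".stl", ".ply")))
    if not paths:
        raise CanalSSMError(f"input stage: no STL/PLY files in {config.input_dir}")
    return [read_mesh(os.path.join(config.input_dir, p)) for p in paths], None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the five-stage analysis and (optionally) write the report bundle."""
    meshes, cohort = _load_meshes(config)
    n = len(meshes)
    log.info("pipeline: %d subjects", n)

    # reference = intermediate-sized (median-extent) canal; for synthetic
    # cohorts it is chosen among ground-truth left canals so the reference is
    # left-sided, as the mirroring convention requires
    candidates = None
    if cohort is not None:
        left = [i for i, p in enumerate(cohort.params) if p.side == "left"]
        candidates = left or None
    ref_idx = choose_reference(meshes, candidates)

    sides, mirrored = [], []
    for i, m in enumerate(meshes):
        if i == ref_idx:
            mirrored.append(m.copy())
            sides.append("left")
            continue
        out, flag = mirror_canal(m, meshes[ref_idx], spacing=config.spacing_mm)
        mirrored.append(out)
        sides.append(flag)

    result = PipelineResult(config=config, reference_index=ref_idx,
                            sides=sides, cohort=cohort)

    for fraction in config.fractions:
        ref_seg = cut_segment(mirrored[ref_idx], fraction)
        corresponded: list[CorrespondedMesh] = []
        icp_rows, rbf_rows = [], []
        for i, m in enumerate(mirrored):
            try:
                seg = cut_segment(m, fraction)
                if i == ref_idx:
                    corresponded.append(CorrespondedMesh(
                        vertices=ref_seg.vertices.copy(), faces=ref_seg.faces.copy(),
                        template_id=ref_idx, residual_mm=0.0, iterations_used=0,
                        converged=True))
                    continue
                icp = icp_align(seg, ref_seg, config.icp_tol_trans_mm,
                                config.icp_tol_rot_deg, config.icp_max_iter)
                icp_rows.append({"subject": i, "fraction": fraction,
                                 "iterations": icp.iterations,
                                 "trans_increment_mm": icp.trans_increment_mm,
                                 "rot_increment_deg": icp.rot_increment_deg,
                                 "residual_mm": icp.residual_mm})
                reg = rbf_register(ref_seg, icp.mesh, tol_mm=config.rbf_tol_mm,
                                   max_iter=config.rbf_max_iter,
                                   n_controls=config.rbf_controls,
                                   template_id=ref_idx)
                rbf_rows.append({"subject": i, "fraction": fraction,
                                 "iterations": reg.iterations_used,
                                 "residual_mm": reg.residual_mm,
                                 "converged": reg.converged})
                corresponded.append(reg)
            except CanalSSMError as exc:
                log.warning("fraction %.2f: skipping subject %d: %s", fraction, i, exc)
        if len(corresponded) < 3:
            raise CanalSSMError(
                f"SSM stage: fewer than 3 subjects survived at fraction {fraction}")

        model = build_ssm(corresponded, fraction=fraction)
        total_var = float(model.eigenvalues.sum())
        degenerate = total_var < _DEGENERATE_VAR_MM2
        if degenerate:
            log.warning("fraction %.2f: degenerate cohort (total shape variance "
                        "%.3g mm^2)", fraction, total_var)
            fr_var = np.zeros_like(model.eigenvalues)
            cum = np.zeros_like(model.eigenvalues)
            nm = 0
            vt = None
        else:
            fr_var, cum = explained_variance(model)
            nm = n_modes_for(model, config.variance_threshold)
            vt = variation_table(model, config.n_pcs, config.spacing_mm,
                                 config.negligible_pct)
        result.fractions[fraction] = FractionResult(
            fraction=fraction, model=model, variance_fractions=fr_var,
            cumulative_variance=cum, n_modes_90=nm, variation=vt,
            degenerate=degenerate, icp_log=pd.DataFrame(icp_rows),
            rbf_log=pd.DataFrame(rbf_rows))

    if config.outdir:
        write_report(result, config.outdir)
    return result


def write_report(result: PipelineResult, outdir: str) -> None:
    """CSV tables per fraction + one JSON summary + a run log of the settings."""
    os.makedirs(outdir, exist_ok=True)
    cfg = result.config
    pd.DataFrame({"subject": range(len(result.sides)),
                  "side": result.sides}).to_csv(
        os.path.join(outdir, "sides.csv"), index=False)
    if result.cohort is not None:
        result.cohort.to_csv(os.path.join(outdir, "ground_truth.csv"))
    result.variance_summary().to_csv(
        os.path.join(outdir, "variance_summary.csv"), index=False)
    icp_all = [fr.icp_log for fr in result.fractions.values() if len(fr.icp_log)]
    if icp_all:
        pd.concat(icp_all).to_csv(os.path.join(outdir, "alignment_log.csv"),
                                  index=False)
    rbf_all = [fr.rbf_log for fr in result.fractions.values() if len(fr.rbf_log)]
    if rbf_all:
        pd.concat(rbf_all).to_csv(os.path.join(outdir, "correspondence_log.csv"),
                                  index=False)
    summary = {"reference_index": result.reference_index,
               "n_subjects": len(result.sides),
               "settings": _config_dict(cfg),
               "fractions": {}}
    for f, fr in sorted(result.fractions.items()):
        tag = f"{int(round(100 * f)):03d}L"
        if fr.variation is not None:
            fr.variation.table.to_csv(
                os.path.join(outdir, f"variation_{tag}.csv"), index=False)
        summary["fractions"][tag] = {
            "n_modes_90": fr.n_modes_90,
            "degenerate": fr.degenerate,
            "variance_pct": [round(100 * v, 3)
                             for v in fr.variance_fractions[:cfg.n_pcs].tolist()],
            "highlights": fr.variation.highlights if fr.variation else {},
        }
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)


def _config_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    pop = d.pop("population", None)
    if pop is not None:
        pop = {k: v for k, v in pop.items()}
        d["population"] = pop
    return _jsonable(d)


def _jsonable(x):
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, float) and not np.isfinite(x):
        return str(x)
    return x
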