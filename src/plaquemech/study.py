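"""Model/Results interface tying the pipeline together.

:class:`ThinSliceModel` is the single-slice estimator: given segmented
contours, a pressure and a layer treatment it runs the axial and
circumferential preconditioning, solves the inflation problem and samples
stress/strain at the quarter-divided extraction nodes.  Its :meth:`fit`
returns an :class:`InflationResults`.

:class:`LayerComparisonStudy` is the cohort-level model: it fits every
slice of every patient under both the multilayer and the single-layer
treatment, assembles the six per-patient comparison tables (plaque / cap /
out-wall x stress / strain) with cohort Mean +/- SD rows and relative
differences (single-layer as base), and runs the paired statistics.  Its
:meth:`fit` returns a :class:`StudyResults` whose :meth:`summary` prints
the comparison the way the per-patient tables are conventionally reported.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .contours import VesselSliceContours, merge_to_single_layer
from .extraction import (RegionNodeSets, cohort_average, extract_slice_values,
                         identify_cap_nodes, quarter_divide, relative_difference,
                         summarize_patient)
from .fem import MMHG_TO_KPA, SolverError
from .materials import MaterialRegistry, default_registry
from .mesh import MeshingError
from .preshrink import PreshrinkError, PreshrinkResult, circumferential_preshrink
from .stats import PairedComparison, paired_t
from .synthetic import SyntheticPatient

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "ThinSliceModel", "InflationResults",
           "LayerComparisonStudy", "StudyResults", "run_comparison_study"]

TABLE_KEYS = ("plaque_stress", "plaque_strain", "cap_stress", "cap_strain",
              "outwall_stress", "outwall_strain")


@dataclass(frozen=True)
class StudyConfig:
    """Resolution and preconditioning settings shared by every slice model."""

    n_rays: int = 36
    n_radial_per_layer: int = 2
    n_slabs: int = 1
    thickness: float = 0.5           # mm
    axial_stretch: float = 1.05
    preshrink_tol: float = 0.005
    solver_tol: float = 1e-8
    n_per_quarter: int = 25
    quarter_anchor_deg: float = 0.0

    @property
    def mesh_options(self) -> dict:
        return dict(n_rays=self.n_rays, n_radial_per_layer=self.n_radial_per_layer,
                    n_slabs=self.n_slabs, thickness=self.thickness)


@dataclass
class InflationResults:
    """Fitted single-slice model: preconditioning, solution, extractions."""

    slice_id: str
    layer_mode: str
    pressure_mmHg: float
    preshrink: PreshrinkResult
    node_sets: RegionNodeSets
    cap_mask: np.ndarray
    values: dict[str, np.ndarray]

    @property
    def solution(self):
        return self.preshrink.solution

    def summary(self) -> str:
        v = self.values
        lines = [
            f"Thin-slice inflation model  [{self.slice_id}, {self.layer_mode}-layer]",
            f"  pressure {self.pressure_mmHg:.1f} mmHg "
            f"({self.pressure_mmHg * MMHG_TO_KPA:.2f} kPa), "
            f"axial stretch {self.solution.axial_stretch:.2f}",
            f"  pre-shrink factor {self.preshrink.shrink_factor:.4f} "
            f"(residual {self.preshrink.residual:.2e}, "
            f"{self.preshrink.iterations} evaluations)",
            f"  Newton iterations {self.solution.newton_iterations}, "
            f"load steps {self.solution.load_steps}, "
            f"J in [{self.solution.j_range[0]:.4f}, {self.solution.j_range[1]:.4f}]",
            f"  inner wall: max stress {v['plaque_stress'].max():8.2f} kPa, "
            f"max strain {v['plaque_strain'].max():.3f}",
            f"  out-wall:   max stress {v['outwall_stress'].max():8.2f} kPa, "
            f"max strain {v['outwall_strain'].max():.3f}",
        ]
        if self.cap_mask.any():
            lines.append(
                f"  cap ({int(self.cap_mask.sum())} nodes): "
                f"max stress {v['cap_stress'].max():8.2f} kPa, "
                f"max strain {v['cap_strain'].max():.3f}")
        return "\n".join(lines)


class ThinSliceModel:
    """One cross-section under one layer treatment.

    Parameters
    ----------
    contours : segmented slice (multilayer; the single-layer treatment is
        applied internally when ``layer_mode='single'``).
    pressure_mmHg : lumen pressure (converted internally to kPa).
    layer_mode : 'multi' or 'single'.
    registry : material parameter sets; defaults to the published values
        with the intima material for the combined single-layer wall.
    """

    def __init__(self, contours: VesselSliceContours, pressure_mmHg: float,
                 layer_mode: str = "multi",
                 registry: MaterialRegistry | None = None,
                 config: StudyConfig | None = None):
        if layer_mode not in ("multi", "single"):
            raise ValueError("layer_mode must be 'multi' or 'single'")
        self.contours = contours.validate()
        self.pressure_mmHg = float(pressure_mmHg)
        self.layer_mode = layer_mode
        self.registry = registry or default_registry()
        self.config = config or StudyConfig()

    def fit(self) -> InflationResults:
        cfg = self.config
        slc = (merge_to_single_layer(self.contours)
               if self.layer_mode == "single" else self.contours)
        pre = circumferential_preshrink(
            slc, self.registry, self.pressure_mmHg * MMHG_TO_KPA,
            axial_stretch=cfg.axial_stretch, tol=cfg.preshrink_tol,
            mesh_options=cfg.mesh_options, solver_tol=cfg.solver_tol)
        sets = quarter_divide(self.contours.lumen, self.contours.adv,
                              n_per_quarter=cfg.n_per_quarter,
                              anchor_deg=cfg.quarter_anchor_deg)
        cap = identify_cap_nodes(sets, self.contours)
        values = extract_slice_values(pre.solution, sets, cap)
        return InflationResults(
            slice_id=self.contours.slice_id, layer_mode=self.layer_mode,
            pressure_mmHg=self.pressure_mmHg, preshrink=pre,
            node_sets=sets, cap_mask=cap, values=values)


@dataclass
class StudyResults:
    """Cohort-level comparison of multilayer vs single-layer models."""

    tables: dict[str, pd.DataFrame]
    paired_tests: dict[str, PairedComparison]
    config: StudyConfig
    n_patients: int
    dropped_slices: list[str]
    dropped_patients: list[str]

    def summary_rows(self) -> dict[str, dict[str, float]]:
        """Cohort Mean +/- SD and relative differences per table."""
        out = {}
        for key, df in self.tables.items():
            row = {}
            for col in ("max_multi", "max_single", "mean_multi", "mean_single"):
                m, sd = cohort_average(df[col].to_numpy())
                row[col], row[col + "_sd"] = m, sd
            row["max_diff_pct"] = relative_difference(row["max_multi"], row["max_single"])
            row["mean_diff_pct"] = relative_difference(row["mean_multi"], row["mean_single"])
            out[key] = row
        return out

    def direction_agreement(self) -> dict[str, float]:
        """Fraction of patients whose multilayer-vs-single-layer effect has
        the expected sign: higher inner-wall/cap stress and strain, lower
        out-wall stress, higher out-wall strain under the multilayer model."""
        expected = {"plaque_stress": 1, "plaque_strain": 1, "cap_stress": 1,
                    "cap_strain": 1, "outwall_stress": -1, "outwall_strain": 1}
        out = {}
        for key, sign in expected.items():
            df = self.tables[key].dropna()
            agree = 0
            for stat in ("max", "mean"):
                d = df[f"{stat}_multi"] - df[f"{stat}_single"]
                agree += int((np.sign(d) == sign).sum())
            out[key] = agree / (2 * len(df)) if len(df) else np.nan
        return out

    def summary(self) -> str:
        lines = ["Multilayer vs single-layer comparison "
                 f"({self.n_patients} patients)",
                 "=" * 74]
        srows = self.summary_rows()
        for key in TABLE_KEYS:
            region, measure = key.split("_")
            unit = "kPa" if measure == "stress" else ""
            r = srows[key]
            t = self.paired_tests.get(key + "_max")
            lines.append(f"{region:>8} {measure:<7} "
                         f"max: {r['max_multi']:8.2f} vs {r['max_single']:8.2f} {unit:<4}"
                         f"({r['max_diff_pct']:+6.2f}%)  "
                         f"mean: {r['mean_multi']:8.2f} vs {r['mean_single']:8.2f} {unit:<4}"
                         f"({r['mean_diff_pct']:+6.2f}%)")
            if t is not None:
                tm = self.paired_tests[key + "_mean"]
                lines.append(f"{'':16} paired t (max):  t={t.t_statistic:6.2f}, "
                             f"df={t.df}, p={t.p_value:.2e}; "
                             f"(mean): t={tm.t_statistic:6.2f}, p={tm.p_value:.2e}")
        if self.dropped_slices:
            lines.append(f"dropped slices: {', '.join(self.dropped_slices)}")
        if self.dropped_patients:
            lines.append(f"dropped patients: {', '.join(self.dropped_patients)}")
        return "\n".join(lines)

    def to_csv(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for key, df in self.tables.items():
            df.to_csv(out / f"table_{key}.csv", float_format="%.6f")
        stats_doc = {name: asdict(t) for name, t in self.paired_tests.items()}
        (out / "paired_tests.json").write_text(json.dumps(stats_doc, indent=1))
        (out / "study_config.json").write_text(json.dumps(asdict(self.config), indent=1))


class LayerComparisonStudy:
    """Fit multilayer and single-layer models to every slice of a cohort."""

    def __init__(self, cohort: list[SyntheticPatient],
                 registry: MaterialRegistry | None = None,
                 config: StudyConfig | None = None):
        self.cohort = cohort
        self.registry = registry or default_registry()
        self.config = config or StudyConfig()

    def fit(self, verbose: bool = False) -> StudyResults:
        rows = {key: [] for key in TABLE_KEYS}
        dropped_slices, dropped_patients = [], []
        kept_patients = 0
        for pat in self.cohort:
            per_mode: dict[str, list] = {"multi": [], "single": []}
            failed = 0
            for slc in pat.slices:
                try:
                    fits = {mode: ThinSliceModel(slc, pat.pressure_mmHg, mode,
                                                 self.registry, self.config).fit()
                            for mode in ("multi", "single")}
                except (SolverError, PreshrinkError, MeshingError) as err:
                    failed += 1
                    dropped_slices.append(slc.slice_id)
                    logger.warning("dropping slice %s: %s", slc.slice_id, err)
                    continue
                for mode in ("multi", "single"):
                    per_mode[mode].append(fits[mode].values)
                if verbose:
                    print(fits["multi"].summary())
            if failed > 0.5 * len(pat.slices):
                dropped_patients.append(pat.patient_id)
                logger.warning("dropping patient %s (%d/%d slices failed)",
                               pat.patient_id, failed, len(pat.slices))
                continue
            kept_patients += 1
            summ = {mode: summarize_patient(per_mode[mode]) for mode in ("multi", "single")}
            for key in TABLE_KEYS:
                mm, ms = summ["multi"][f"max_{key}"], summ["single"][f"max_{key}"]
                em, es = summ["multi"][f"mean_{key}"], summ["single"][f"mean_{key}"]
                rows[key].append({
                    "patient": pat.patient_id,
                    "max_multi": mm, "max_single": ms,
                    "max_diff_pct": relative_difference(mm, ms) if ms else np.nan,
                    "mean_multi": em, "mean_single": es,
                    "mean_diff_pct": relative_difference(em, es) if es else np.nan,
                })
        tables = {key: pd.DataFrame(r).set_index("patient") for key, r in rows.items()}
        paired = {}
        for key, df in tables.items():
            d = df.dropna()
            for stat in ("max", "mean"):
                try:
                    paired[f"{key}_{stat}"] = paired_t(d[f"{stat}_multi"].to_numpy(),
                                                       d[f"{stat}_single"].to_numpy())
                except ValueError as err:
                    logger.info("paired test %s_%s degenerate: %s", key, stat, err)
        return StudyResults(tables=tables, paired_tests=paired, config=self.config,
                            n_patients=kept_patients, dropped_slices=dropped_slices,
                            dropped_patients=dropped_patients)


def run_comparison_study(cohort: list[SyntheticPatient],
                         registry: MaterialRegistry | None = None,
                         config: StudyConfig | None = None,
                         out_dir: str | Path | None = None) -> StudyResults:
    """Functional wrapper: fit the study and optionally write the CSV/JSON
    outputs."""
    results = LayerComparisonStudy(cohort, registry, config).fit()
    if out_dir is not None:
        results.to_csv(out_dir)
    return results
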