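"""DVH construction, plan-quality metrics, plan summation, and the
clinical organ-at-risk protocol checker.

Metric conventions:

* ``D_q%`` is the dose received by the hottest q% of a structure,
  computed by linear interpolation between the sorted voxel doses
  (``numpy.percentile`` at the 100-q quantile), so values are
  reproducible bit-for-bit.
* ``V_xGy`` is the fraction (%) of structure voxels receiving >= x Gy;
  ``V_x%`` measures against x% of a prescription dose.
* Homogeneity index ``HI = (D_2% - D_98%) / D_50%``; conformity indices
  ``CI = V_95% / V_PTV`` and ``CI_50% = V_50% / V_PTV`` where the
  isodose volumes are measured over the whole patient, not the PTV.
* ``EQD2`` converts a summed dose to the equi-effective dose in 2 Gy
  fractions with the linear-quadratic model:
  ``EQD2 = D * (d + alpha/beta) / (2 + alpha/beta)``, d = D/n per voxel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import geometry
from .errors import GridMismatchError, StructureError
from .grid import StructureSet, VoxelGrid
from .wishlist import PrescriptionContext

#: Margin around the boost volume excluded when reporting PTV-LN dose
#: statistics (the boost region would otherwise dominate D_2%/HI).
SIB_REPORT_MARGIN_MM = 20.0


# --------------------------------------------------------------------------
# dose-volume primitives
# --------------------------------------------------------------------------


def _masked(dose: np.ndarray, mask: np.ndarray) -> np.ndarray:
    dose = np.asarray(dose, float)
    mask = np.asarray(mask, bool)
    if dose.shape != mask.shape:
        raise GridMismatchError(f"dose shape {dose.shape} != mask shape {mask.shape}")
    d = dose[mask]
    if d.size == 0:
        raise StructureError("metric requested on an empty structure")
    return d


@dataclass
class DVH:
    """Cumulative dose-volume histogram of one structure."""

    structure: str
    bin_edges_gy: np.ndarray        # length nbins+1
    cumulative_volume: np.ndarray   # fraction in [0,1], at each LEFT edge

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "dose_gy": self.bin_edges_gy[:-1],
            "volume_fraction": self.cumulative_volume,
        })


def dvh(dose, mask, bin_width_gy: float = 0.1, structure: str = "", max_gy=None) -> DVH:
    """Cumulative DVH: volume fraction receiving at least each bin-edge dose."""
    d = _masked(dose, mask)
    if bin_width_gy <= 0:
        raise ValueError("bin width must be > 0")
    top = float(max_gy if max_gy is not None else d.max() + bin_width_gy)
    edges = np.arange(0.0, top + bin_width_gy, bin_width_gy)
    counts, _ = np.histogram(d, bins=edges)
    # cumulative from the top: fraction with dose >= left edge
    cum = counts[::-1].cumsum()[::-1] / d.size
    return DVH(structure, edges, cum)


def d_at_volume(dose, mask, q_percent: float) -> float:
    """D_q%: dose to the hottest q% of the structure (interpolated quantile)."""
    if not 0 < q_percent < 100:
        raise ValueError(f"q must be in (0, 100), got {q_percent}")
    d = _masked(dose, mask)
    return float(np.percentile(d, 100.0 - q_percent))


def v_at_dose(dose, mask, threshold_gy: float) -> float:
    """V_xGy: percent of structure voxels receiving at least the threshold."""
    d = _masked(dose, mask)
    return float(100.0 * np.mean(d >= threshold_gy))


def v_total_at_fraction(dose, external, grid: VoxelGrid, rx_gy: float,
                        fraction: float) -> float:
    """Total body volume (ml) irradiated at >= fraction * prescription."""
    if rx_gy <= 0:
        raise ValueError("prescription dose must be > 0")
    d = _masked(dose, external)
    return float(np.sum(d >= fraction * rx_gy)) * grid.voxel_volume_ml


def hi(dose, mask) -> float:
    """Homogeneity index (D_2% - D_98%) / D_50%; 0 for uniform dose."""
    d50 = d_at_volume(dose, mask, 50.0)
    if d50 <= 0:
        raise ValueError("median dose is zero; HI undefined")
    return (d_at_volume(dose, mask, 2.0) - d_at_volume(dose, mask, 98.0)) / d50


def ci(dose, ptv_mask, external, grid: VoxelGrid, rx_gy: float) -> float:
    """Conformity index V_95% / V_PTV, isodose volume over the whole body."""
    return _conformity(dose, ptv_mask, external, grid, rx_gy, 0.95)


def ci50(dose, ptv_mask, external, grid: VoxelGrid, rx_gy: float) -> float:
    """Low-dose conformity V_50% / V_PTV (dose-spill measure)."""
    return _conformity(dose, ptv_mask, external, grid, rx_gy, 0.50)


def _conformity(dose, ptv_mask, external, grid, rx_gy, fraction):
    ptv_mask = np.asarray(ptv_mask, bool)
    if not ptv_mask.any():
        raise StructureError("PTV mask is empty")
    v_iso = v_total_at_fraction(dose, external, grid, rx_gy, fraction)
    v_ptv = float(ptv_mask.sum()) * grid.voxel_volume_ml
    return v_iso / v_ptv


def sum_plans(dose_phase1: np.ndarray, dose_phase2: np.ndarray) -> np.ndarray:
    """Voxelwise sum of the two phase doses."""
    a = np.asarray(dose_phase1, float)
    b = np.asarray(dose_phase2, float)
    if a.shape != b.shape:
        raise GridMismatchError(f"dose shapes differ: {a.shape} vs {b.shape}")
    return a + b


def eqd2(dose_total: np.ndarray, n_fractions: int, alpha_beta: float = 3.0) -> np.ndarray:
    """Equi-effective dose in 2 Gy fractions (voxelwise LQ conversion)."""
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    if alpha_beta <= 0:
        raise ValueError("alpha/beta must be > 0")
    D = np.asarray(dose_total, float)
    d = D / n_fractions
    return D * (d + alpha_beta) / (2.0 + alpha_beta)


# --------------------------------------------------------------------------
# clinical protocol (packaged organ-at-risk constraint table)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ProtocolConstraint:
    structure: str
    metric: str                 # "D_max" or "V_gy"
    limit: float                # Gy for D_max, % for V_gy
    dose_gy: Optional[float] = None  # threshold for V_gy

    @property
    def label(self) -> str:
        if self.metric == "D_max":
            return f"{self.structure} D_max <= {self.limit:g} Gy"
        return f"{self.structure} V_{self.dose_gy:g}Gy <= {self.limit:g}%"


@dataclass
class ClinicalProtocol:
    name: str
    constraints: List[ProtocolConstraint]

    @classmethod
    def builtin(cls) -> "ClinicalProtocol":
        text = resources.files("lexiplan.data").joinpath("oar_protocol.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def from_dict(cls, d: dict) -> "ClinicalProtocol":
        cons = []
        for row in d["constraints"]:
            if row["metric"] == "D_max":
                cons.append(ProtocolConstraint(row["structure"], "D_max",
                                               float(row["limit_gy"])))
            elif row["metric"] == "V_gy":
                pct = float(row["limit_pct"])
                if not 0 <= pct <= 100:
                    raise ValueError(f"percent limit out of range: {pct}")
                cons.append(ProtocolConstraint(row["structure"], "V_gy", pct,
                                               dose_gy=float(row["dose_gy"])))
            else:
                raise ValueError(f"unknown protocol metric {row['metric']!r}")
        if any(c.limit <= 0 for c in cons):
            raise ValueError("protocol thresholds must be positive")
        return cls(d.get("name", "protocol"), cons)

    @classmethod
    def load(cls, path) -> "ClinicalProtocol":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _protocol_mask(structures: StructureSet, name: str) -> np.ndarray:
    if name in structures:
        return structures[name]
    if name == "femoral_heads":
        return structures["femoral_head_left"] | structures["femoral_head_right"]
    raise StructureError(f"protocol structure {name!r} missing from structure set")


def check_protocol(summed_dose: np.ndarray, structures: StructureSet,
                   protocol: ClinicalProtocol = None,
                   near_max_percent: Optional[float] = None) -> pd.DataFrame:
    """Evaluate every protocol constraint on the summed dose.

    ``D_max`` is the true voxel maximum by default; pass e.g.
    ``near_max_percent=2`` to use the near-maximum D_2% variant instead.
    Returns a ledger with measured value, threshold and pass flag.
    """
    protocol = protocol or ClinicalProtocol.builtin()
    rows = []
    for c in protocol.constraints:
        mask = _protocol_mask(structures, c.structure)
        if c.metric == "D_max":
            if near_max_percent is None:
                measured = float(_masked(summed_dose, mask).max())
            else:
                measured = d_at_volume(summed_dose, mask, near_max_percent)
            unit = "Gy"
        else:
            measured = v_at_dose(summed_dose, mask, c.dose_gy)
            unit = "%"
        rows.append({"constraint": c.label, "structure": c.structure,
                     "metric": c.metric, "dose_gy": c.dose_gy,
                     "measured": measured, "threshold": c.limit, "unit": unit,
                     "pass": bool(measured <= c.limit)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# target metrics report
# --------------------------------------------------------------------------


@dataclass
class MetricsReport:
    """Per-structure dose statistics plus target HI/CI and the protocol ledger."""

    structures: pd.DataFrame         # D2/D98/D50/Dmean/Dmax/V95 per structure
    targets: pd.DataFrame            # HI/CI/CI50 and coverage per target/phase
    protocol: pd.DataFrame
    notes: Dict[str, str] = field(default_factory=dict)

    @property
    def protocol_pass(self) -> bool:
        return bool(self.protocol["pass"].all())

    def save(self, directory):
        """Write the report as CSV tables plus one combined JSON document."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.structures.to_csv(directory / "structure_metrics.csv", index=False)
        self.targets.to_csv(directory / "target_metrics.csv", index=False)
        self.protocol.to_csv(directory / "protocol_ledger.csv", index=False)
        combined = {
            "structures": self.structures.to_dict(orient="records"),
            "targets": self.targets.to_dict(orient="records"),
            "protocol": self.protocol.to_dict(orient="records"),
            "protocol_pass": self.protocol_pass,
            "notes": self.notes,
        }
        (directory / "metrics.json").write_text(
            json.dumps(combined, indent=2, default=float))


def structure_statistics(dose, mask, rx_gy: Optional[float] = None) -> dict:
    """The standard per-structure row: quantile doses, mean, max, coverage."""
    d = _masked(dose, mask)
    out = {
        "D_2%": float(np.percentile(d, 98.0)),
        "D_50%": float(np.percentile(d, 50.0)),
        "D_98%": float(np.percentile(d, 2.0)),
        "D_mean": float(d.mean()),
        "D_max": float(d.max()),
    }
    if rx_gy is not None:
        out["V_95%"] = float(100.0 * np.mean(d >= 0.95 * rx_gy))
    return out


def target_metrics(
    summed_dose: np.ndarray,
    phase_doses: Dict[int, np.ndarray],
    structures: StructureSet,
    context: PrescriptionContext = None,
) -> MetricsReport:
    """Full plan-quality report for a two-phase plan.

    Coverage (V_95%) is assessed per target against its summed
    prescription: PTV-P against D_high + boost (73 Gy by default), PTV-LN
    against D_low; per-phase coverage against the phase prescriptions.
    PTV-LN statistics are reported on PTV-LN minus the boost volume plus
    a 20 mm margin, so the boost region does not contaminate them.
    """
    context = context or PrescriptionContext()
    grid = structures.grid
    external = structures["external"]

    ptv_p = structures["PTV-P"]
    ptv_ln = structures["PTV-LN"]
    sib_expanded = geometry.expand(ptv_p, SIB_REPORT_MARGIN_MM, grid)
    ln_report = geometry.subtract(ptv_ln, sib_expanded)
    notes = {}
    if not ln_report.any():
        notes["PTV-LN"] = "reporting mask empty after SIB subtraction; metrics absent"

    rx = {
        "PTV-P": context.summed_prescription_ptv_p,
        "PTV-LN": context.summed_prescription_ptv_ln,
    }
    phase_rx = {
        (1, "PTV-P"): context.d_high,
        (1, "PTV-LN"): context.d_low,
        (2, "PTV-P"): context.d_boost,
    }

    srows = []
    for name in structures.names:
        if name == "external":
            continue
        row = {"structure": name, "dose": "summed"}
        row.update(structure_statistics(summed_dose, structures[name], rx.get(name)))
        srows.append(row)

    trows = []
    for target, report_mask in (("PTV-P", ptv_p), ("PTV-LN", ln_report)):
        target_rx = rx[target]
        entry = {"target": target, "dose": "summed", "rx_gy": target_rx}
        entry["V_95%"] = float(100.0 * np.mean(summed_dose[structures[target]] >= 0.95 * target_rx))
        if report_mask.any():
            entry["HI"] = hi(summed_dose, report_mask)
            entry["D_2%"] = d_at_volume(summed_dose, report_mask, 2.0)
            entry["D_mean"] = float(summed_dose[report_mask].mean())
        trows.append(entry)
    for (phase, target), rx_phase in phase_rx.items():
        if phase not in phase_doses:
            continue
        dose_p = phase_doses[phase]
        mask = structures[target]
        report_mask = ln_report if target == "PTV-LN" else mask
        entry = {"target": target, "dose": f"phase{phase}", "rx_gy": rx_phase}
        entry["V_95%"] = float(100.0 * np.mean(dose_p[mask] >= 0.95 * rx_phase))
        entry["CI"] = ci(dose_p, mask, external, grid, rx_phase)
        entry["CI_50%"] = ci50(dose_p, mask, external, grid, rx_phase)
        if report_mask.any():
            entry["HI"] = hi(dose_p, report_mask)
            entry["D_2%"] = d_at_volume(dose_p, report_mask, 2.0)
            entry["D_mean"] = float(dose_p[report_mask].mean())
        trows.append(entry)

    protocol_df = check_protocol(summed_dose, structures)
    return MetricsReport(pd.DataFrame(srows), pd.DataFrame(trows), protocol_df, notes)


def rectum_hypofractionation_metrics(
    summed_dose: np.ndarray,
    structures: StructureSet,
    context: PrescriptionContext = None,
    alpha_beta: float = 3.0,
    convert: str = "dose",
) -> Dict[str, float]:
    """Rectal V_70Gy / V_55Gy adjusted for hypofractionation.

    With ``convert="dose"`` (default) the summed dose grid is converted
    voxelwise to EQD2 over the total fraction count and the thresholds
    applied unchanged; ``convert="threshold"`` instead converts the 70
    and 55 Gy thresholds to the physical-dose scale and evaluates them
    on the raw summed dose.  Both readings give identical results when
    the dose per fraction is exactly 2 Gy.
    """
    context = context or PrescriptionContext()
    n = context.total_fractions
    mask = structures["rectum"]
    if convert == "dose":
        adj = eqd2(summed_dose, n, alpha_beta)
        return {"V_70Gy": v_at_dose(adj, mask, 70.0), "V_55Gy": v_at_dose(adj, mask, 55.0)}
    if convert != "threshold":
        raise ValueError("convert must be 'dose' or 'threshold'")

    def physical(eqd2_gy):
        # invert D*(D/n + ab)/(2+ab) = eqd2 for the physical dose D
        a, b, c_ = 1.0 / n, alpha_beta, -eqd2_gy * (2.0 + alpha_beta)
        return (-b + np.sqrt(b * b - 4 * a * c_)) / (2 * a)

    return {
        "V_70Gy": v_at_dose(summed_dose, mask, physical(70.0)),
        "V_55Gy": v_at_dose(summed_dose, mask, physical(55.0)),
    }
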