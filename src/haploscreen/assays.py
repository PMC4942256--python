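"""Assay quantifications: PE fraction, 14C flux, calcein leakage, viability
and delta-delta-CT relative expression."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def pe_fraction(pi_pe: float, pi_other: float) -> float:
    """Fraction of total phospholipid phosphorus found in the PE spot:
    Pi(PE) / (Pi(PE) + Pi(other)).  Scale-invariant, in [0, 1]."""
    if pi_pe < 0 or pi_other < 0:
        raise ValueError("phosphate quantities must be non-negative")
    total = pi_pe + pi_other
    if total == 0:
        raise ValueError("both phosphate quantities are zero")
    return pi_pe / total


def c14_flux(cpm_pe: float, total_pi: float) -> float:
    """14C-PE scintillation counts normalized to total phospholipid content
    (cpm per nmol phosphate)."""
    if total_pi <= 0:
        raise ValueError("total phospholipid phosphate must be positive")
    return cpm_pe / total_pi


def relative_flux(cpm_pe: float, total_pi: float, cpm_vehicle: float, pi_vehicle: float) -> float:
    """Flux relative to the vehicle-treated sample (vehicle maps to 1)."""
    return c14_flux(cpm_pe, total_pi) / c14_flux(cpm_vehicle, pi_vehicle)


@dataclass
class LeakagePoint:
    time: float
    percent: float
    out_of_range: bool


def leakage_percent(
    times,
    fluorescence,
    vehicle,
    triton,
) -> list[LeakagePoint]:
    """Calcein-leakage percentage per time point.

    Fluorescence is normalized between the DMSO-vehicle series (0% leakage)
    and the detergent-lysed series (100% leakage):
    100 * (F - F_vehicle) / (F_triton - F_vehicle).  Background subtraction
    per condition is assumed done upstream.  Values outside [0, 100] are
    reported unclipped with an out-of-range flag (instrument noise can
    undershoot or overshoot the references).
    """
    times = np.asarray(times, dtype=float)
    f = np.asarray(fluorescence, dtype=float)
    f0 = np.asarray(vehicle, dtype=float)
    f100 = np.asarray(triton, dtype=float)
    if not (times.shape == f.shape == f0.shape == f100.shape):
        raise ValueError("all series must have equal length")
    if np.any(f100 <= f0):
        bad = times[f100 <= f0]
        raise ValueError(f"100% reference not above 0% reference at t={bad.tolist()}")
    pct = 100.0 * (f - f0) / (f100 - f0)
    return [
        LeakagePoint(float(t), float(p), bool(p < 0.0 or p > 100.0))
        for t, p in zip(times, pct)
    ]


def relative_viability(signal: float, vehicle_signal: float) -> float:
    """Luminescence viability normalized so the vehicle-treated sample is 1."""
    if vehicle_signal <= 0:
        raise ValueError("vehicle signal must be positive")
    return signal / vehicle_signal


@dataclass
class DdctResult:
    """Relative expression by the delta-delta-CT method.

    ``ddct`` follows the standard convention (test minus calibrator, so an
    expression increase gives a NEGATIVE ddct and fold = 2**(-ddct) > 1).
    ``reported_magnitude`` is |mean ddct| with fold 2**|ddct|, the
    presentation used when an increase is reported as a positive number.
    """

    ddct_per_pair: list[float]
    mean_ddct: float
    fold_change: float
    reported_magnitude: float
    reported_fold: float


def ddct_relative_expression(
    test_target_ct,
    test_reference_ct,
    calibrator_target_ct,
    calibrator_reference_ct,
) -> DdctResult:
    """delta-delta-CT with a reference (housekeeping) gene, e.g. GAPDH.

    Inputs are per-primer-pair CT values (scalars or equal-length sequences,
    one entry per primer pair; replicate CTs should be averaged upstream).
    dCT = CT_target - CT_reference per sample; ddCT = dCT_test -
    dCT_calibrator; fold = 2**(-ddCT), averaged over primer pairs.
    """
    tt = np.atleast_1d(np.asarray(test_target_ct, dtype=float))
    tr = np.atleast_1d(np.asarray(test_reference_ct, dtype=float))
    ct = np.atleast_1d(np.asarray(calibrator_target_ct, dtype=float))
    cr = np.atleast_1d(np.asarray(calibrator_reference_ct, dtype=float))
    if not (tt.shape == tr.shape == ct.shape == cr.shape):
        raise ValueError("mismatched primer pairs between test and calibrator")
    for arr in (tt, tr, ct, cr):
        if np.any((arr <= 0) | (arr >= 45)):
            raise ValueError("CT values must lie in (0, 45)")
    ddct = (tt - tr) - (ct - cr)
    mean_ddct = float(np.mean(ddct))
    return DdctResult(
        ddct_per_pair=[float(x) for x in ddct],
        mean_ddct=mean_ddct,
        fold_change=float(2.0 ** (-mean_ddct)),
        reported_magnitude=abs(mean_ddct),
        reported_fold=float(2.0 ** abs(mean_ddct)),
    )
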