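"""Tube-voltage conversion factors for kVp-independent PCAT_MA.

The conversion factor at tube voltage ``i`` relative to the 120 kVp
reference is the attenuation ratio

    k_i = PCAT_MA,i / PCAT_MA,120

estimated from IR-reconstructed datasets, and a measurement at voltage
``i`` is re-expressed at the reference by

    I_120 = I_i / k_i.

Per-vessel factors are averaged with equal weight across vessels; tables
from different scanners are combined per kVp as the mean of the scanner
factors with a standard-error-of-the-mean uncertainty. Reported factors
are rounded to 3 decimals (half away from zero); full precision is kept
internally.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .measurement import PCATMeasurement

DEFAULT_REFERENCE_KVP = 120


class CalibrationError(ValueError):
    pass


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Decimal rounding, ties away from zero (the table-reporting rule).

    Plain ``round`` rounds ties to even on the binary representation, which
    turns e.g. a mean of 1.2665 into 1.266; reporting uses half-up on the
    decimal value instead. The value is first snapped to ``ndigits + 7``
    decimals so binary representation error (1.2665 stored as
    1.26649999...) cannot flip a decimal tie.
    """
    guard = Decimal(1).scaleb(-(ndigits + 7))
    q = Decimal(1).scaleb(-ndigits)
    snapped = Decimal(repr(float(x))).quantize(guard, rounding=ROUND_HALF_UP)
    return float(snapped.quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Factor:
    k: float
    sd: float = 0.0


@dataclass
class ConversionTable:
    """Per-kVp conversion factors (with uncertainties) to one reference kVp."""

    reference_kvp: int
    factors: dict[int, Factor]
    scanner_label: str = "unknown"
    source: tuple[str, ...] = ()
    sd_method: str = "exact"

    def __post_init__(self) -> None:
        self.factors = {int(k): v if isinstance(v, Factor) else Factor(*v)
                        for k, v in self.factors.items()}
        ref = self.factors.get(self.reference_kvp)
        if ref is None or ref.k != 1.0 or ref.sd != 0.0:
            # normalisation: the reference entry is (1, 0) by definition
            self.factors[self.reference_kvp] = Factor(1.0, 0.0)
        if any(f.k <= 0 for f in self.factors.values()):
            raise CalibrationError("all conversion factors must be > 0")

    def k(self, kvp: int) -> float:
        if kvp not in self.factors:
            raise CalibrationError(
                f"{kvp} kVp missing from conversion table (has {sorted(self.factors)})"
            )
        return self.factors[kvp].k

    def rounded(self, ndigits: int = 3) -> dict[int, tuple[float, float]]:
        return {
            kvp: (round_half_up(f.k, ndigits), round_half_up(f.sd, ndigits))
            for kvp, f in sorted(self.factors.items())
        }

    # -- IO ------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"kvp": kvp, "k": f.k, "sd": f.sd, "scanner": self.scanner_label,
             "reference_kvp": self.reference_kvp}
            for kvp, f in sorted(self.factors.items())
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9f")

    @classmethod
    def from_csv(cls, path) -> "ConversionTable":
        df = pd.read_csv(path)
        factors = {int(r["kvp"]): Factor(float(r["k"]), float(r["sd"])) for _, r in df.iterrows()}
        return cls(
            reference_kvp=int(df["reference_kvp"].iloc[0]),
            factors=factors,
            scanner_label=str(df["scanner"].iloc[0]),
        )

    def to_json(self, path) -> None:
        payload = {
            "reference_kvp": self.reference_kvp,
            "scanner_label": self.scanner_label,
            "source": list(self.source),
            "sd_method": self.sd_method,
            "factors": {str(k): [f.k, f.sd] for k, f in sorted(self.factors.items())},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "ConversionTable":
        d = json.loads(Path(path).read_text())
        return cls(
            reference_kvp=int(d["reference_kvp"]),
            factors={int(k): Factor(*v) for k, v in d["factors"].items()},
            scanner_label=d.get("scanner_label", "unknown"),
            source=tuple(d.get("source", ())),
            sd_method=d.get("sd_method", "exact"),
        )


# ---------------------------------------------------------------------------
# Core arithmetic
# ---------------------------------------------------------------------------

def conversion_factor(pcat_at_i: float, pcat_at_ref: float) -> float:
    """k_i = PCAT_MA at voltage i over PCAT_MA at the reference voltage."""
    if pcat_at_ref == 0:
        raise CalibrationError("reference PCAT_MA is zero; conversion factor undefined")
    if pcat_at_i >= 0 or pcat_at_ref >= 0:
        warnings.warn(
            "conversion factors are defined for adipose (negative-HU) attenuation; "
            f"got ({pcat_at_i}, {pcat_at_ref})",
            stacklevel=2,
        )
    return pcat_at_i / pcat_at_ref


def apply_conversion(value_at_i: float, k_i: float) -> float:
    """Re-express an attenuation measured at voltage i at the reference: I / k_i."""
    if k_i <= 0:
        raise CalibrationError(f"conversion factor must be > 0, got {k_i}")
    return value_at_i / k_i


# ---------------------------------------------------------------------------
# Estimation from measurements
# ---------------------------------------------------------------------------

def _by_vessel(
    measurements: list[PCATMeasurement], recon_filter: str | None
) -> dict[str, dict[int, float]]:
    table: dict[str, dict[int, float]] = {}
    for m in measurements:
        if recon_filter is not None and m.recon != recon_filter:
            continue
        per = table.setdefault(m.vessel_id, {})
        if m.kvp in per:
            raise CalibrationError(
                f"vessel {m.vessel_id!r} has more than one measurement at {m.kvp} kVp "
                f"under recon {recon_filter!r}"
            )
        per[m.kvp] = m.pcat_ma_hu
    return table


def estimate_factors(
    measurements: list[PCATMeasurement],
    reference_kvp: int = DEFAULT_REFERENCE_KVP,
    recon_filter: str | None = "IR",
    scanner_label: str = "unknown",
    sd_method: str = "propagation",
    n_boot: int = 1000,
    seed: int = 0,
) -> ConversionTable:
    """Estimate per-kVp conversion factors from a set of PCAT measurements.

    Per vessel, ``k_i`` is the ratio of its PCAT_MA at kVp ``i`` to its
    PCAT_MA at the reference; the table factor is the unweighted mean over
    vessels. Factors are estimated from the ``recon_filter`` datasets (IR
    by default). Vessels missing any kVp are dropped listwise.

    The per-kVp uncertainty is an interpretation (the exact method behind
    the published tables is not recoverable) and is selectable:

    - ``"propagation"`` (default): first-order delta-method SD of the ratio
      of the across-vessel means, including the i/reference covariance;
    - ``"sample"``: sample SD of the per-vessel ratios;
    - ``"bootstrap"``: SD of the mean ratio over ``n_boot`` seeded vessel
      resamples.
    """
    if recon_filter is not None:
        if not any(m.recon == recon_filter for m in measurements):
            raise CalibrationError(f"no measurements with recon {recon_filter!r}")
    per_vessel = _by_vessel(measurements, recon_filter)
    kvps = sorted({kvp for per in per_vessel.values() for kvp in per})
    if reference_kvp not in kvps:
        raise CalibrationError(f"no measurement at the reference {reference_kvp} kVp")
    complete = {
        vid: per for vid, per in per_vessel.items() if all(k in per for k in kvps)
    }
    if not complete:
        raise CalibrationError("no vessel has a complete set of kVp measurements")

    vids = sorted(complete)
    values = np.array([[complete[v][k] for k in kvps] for v in vids])  # vessels x kvps
    ref_col = kvps.index(reference_kvp)
    ratios = values / values[:, [ref_col]]
    n = len(vids)

    factors: dict[int, Factor] = {}
    rng = np.random.default_rng([int(seed), 1409])
    for j, kvp in enumerate(kvps):
        if kvp == reference_kvp:
            factors[kvp] = Factor(1.0, 0.0)
            continue
        k_mean = float(ratios[:, j].mean())
        if n < 2:
            sd = 0.0
        elif sd_method == "sample":
            sd = float(ratios[:, j].std(ddof=1))
        elif sd_method == "bootstrap":
            picks = rng.integers(0, n, size=(n_boot, n))
            boot = ratios[picks, j].mean(axis=1)
            sd = float(boot.std(ddof=1))
        elif sd_method == "propagation":
            xi, xr = values[:, j], values[:, ref_col]
            mi, mr = xi.mean(), xr.mean()
            var_mi = xi.var(ddof=1) / n
            var_mr = xr.var(ddof=1) / n
            cov = np.cov(xi, xr, ddof=1)[0, 1] / n
            rel = var_mi / mi**2 + var_mr / mr**2 - 2 * cov / (mi * mr)
            sd = float(abs(mi / mr) * np.sqrt(max(rel, 0.0)))
        else:
            raise CalibrationError(f"unknown sd_method {sd_method!r}")
        factors[kvp] = Factor(k_mean, sd)

    return ConversionTable(
        reference_kvp=reference_kvp,
        factors=factors,
        scanner_label=scanner_label,
        source=tuple(vids),
        sd_method=sd_method,
    )


def average_tables(tables: list[ConversionTable]) -> ConversionTable:
    """Combine per-scanner tables: mean factor per kVp, SE-of-means uncertainty.

    The combined sd at each kVp is the sample SD of the scanner factors
    divided by sqrt(number of scanners).
    """
    if len(tables) < 2:
        raise CalibrationError("averaging needs at least 2 tables")
    ref = tables[0].reference_kvp
    kvps = sorted(tables[0].factors)
    for t in tables[1:]:
        if t.reference_kvp != ref or sorted(t.factors) != kvps:
            raise CalibrationError("tables have mismatched kVp sets or reference")
    n = len(tables)
    factors = {}
    for kvp in kvps:
        ks = np.array([t.factors[kvp].k for t in tables])
        if kvp == ref:
            factors[kvp] = Factor(1.0, 0.0)
        else:
            factors[kvp] = Factor(float(ks.mean()), float(ks.std(ddof=1) / np.sqrt(n)))
    return ConversionTable(
        reference_kvp=ref,
        factors=factors,
        scanner_label="average",
        source=tuple(t.scanner_label for t in tables),
        sd_method="se-of-means",
    )


def correct_measurement(m: PCATMeasurement, table: ConversionTable) -> PCATMeasurement:
    """Re-express a measurement at the table's reference kVp via I / k."""
    k = table.k(m.kvp)
    return replace(
        m,
        pcat_ma_hu=apply_conversion(m.pcat_ma_hu, k),
        kvp=table.reference_kvp,
        corrected_from_kvp=m.kvp,
    )
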