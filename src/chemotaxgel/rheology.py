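"""Viscoelastic summaries from oscillatory rheometer sweeps.

Collagen gels are characterized by a strain-amplitude sweep (to find the
linear viscoelastic region, LVER), then a frequency sweep inside the LVER.
The headline numbers are the 1 Hz storage and loss moduli G' and G'', the
loss tangent tan(delta) = G''/G', and the dynamic Young's modulus

    E'(w) = 2 * G'(w) * (1 + nu),

with nu = 0.5 (near-incompressible hydrated network), i.e. E' = 3 G'.
Uncertainty in E' is propagated linearly from the replicate variability of
G': sd(E') = 2 * (1 + nu) * sd(G').

The loss tangent is computed from the mean moduli (the ratio of means), not
the mean of per-replicate ratios; the per-replicate ratios are also exposed
on the summary for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FrequencySweep",
    "StrainSweep",
    "LVERResult",
    "RheologySummary",
    "find_lver",
    "moduli_at_frequency",
    "summarize",
    "summary_from_moduli",
    "read_frequency_sweeps",
    "read_strain_sweep",
]


def _check_sweep(xname, x, gp, gpp):
    x = np.asarray(x, dtype=float)
    gp = np.asarray(gp, dtype=float)
    gpp = np.asarray(gpp, dtype=float)
    if x.ndim != 1 or len(x) != len(gp) or len(x) != len(gpp):
        raise ValueError(f"{xname}, G' and G'' must be 1D arrays of equal length")
    if np.any(np.diff(x) <= 0):
        raise ValueError(f"{xname} must be strictly increasing")
    if np.any(gp <= 0) or np.any(gpp < 0):
        raise ValueError("moduli must be positive (G' > 0, G'' >= 0)")
    return x, gp, gpp


@dataclass
class FrequencySweep:
    """G'(f), G''(f) over an ascending frequency grid (Hz), one replicate."""

    frequencies: np.ndarray
    storage_modulus: np.ndarray
    loss_modulus: np.ndarray
    replicate_id: str = ""

    def __post_init__(self):
        self.frequencies, self.storage_modulus, self.loss_modulus = _check_sweep(
            "frequencies", self.frequencies, self.storage_modulus, self.loss_modulus
        )


@dataclass
class StrainSweep:
    """G', G'' over an ascending strain-amplitude grid (%)."""

    strain_amplitudes: np.ndarray
    storage_modulus: np.ndarray
    loss_modulus: np.ndarray

    def __post_init__(self):
        self.strain_amplitudes, self.storage_modulus, self.loss_modulus = _check_sweep(
            "strain_amplitudes",
            self.strain_amplitudes,
            self.storage_modulus,
            self.loss_modulus,
        )


@dataclass
class LVERResult:
    """Outcome of LVER selection on a strain sweep.

    ``strain_range`` is ``(low, high)`` in % strain or ``None`` when even the
    first point deviates from the low-strain plateau beyond tolerance.
    ``recommended_strain`` is the log-scale midpoint of the range.
    """

    strain_range: tuple[float, float] | None
    recommended_strain: float | None
    plateau_modulus: float
    n_points: int
    diagnostic: str = ""


@dataclass
class RheologySummary:
    G_prime_1Hz: float
    G_prime_sd: float
    G_double_prime_1Hz: float
    G_double_prime_sd: float
    loss_tangent: float
    poisson_ratio: float
    E_prime: float
    E_prime_sd: float
    n_replicates: int
    frequency_hz: float = 1.0
    per_replicate_loss_tangent: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "frequency_hz": self.frequency_hz,
            "G_prime_pa": self.G_prime_1Hz,
            "G_prime_sd_pa": self.G_prime_sd,
            "G_double_prime_pa": self.G_double_prime_1Hz,
            "G_double_prime_sd_pa": self.G_double_prime_sd,
            "loss_tangent": self.loss_tangent,
            "per_replicate_loss_tangent": list(self.per_replicate_loss_tangent),
            "poisson_ratio": self.poisson_ratio,
            "E_prime_pa": self.E_prime,
            "E_prime_sd_pa": self.E_prime_sd,
            "n_replicates": self.n_replicates,
        }


def find_lver(sweep: StrainSweep, tolerance: float = 0.05) -> LVERResult:
    """Largest leading strain range where G' stays within the plateau band.

    The low-strain plateau is the median of the first three G' points; the
    LVER is the maximal run of leading points with
    ``|G' - plateau| <= tolerance * plateau``.
    """
    if len(sweep.strain_amplitudes) < 5:
        raise ValueError("need at least 5 strain amplitudes")
    gp = sweep.storage_modulus
    plateau = float(np.median(gp[:3]))
    within = np.abs(gp - plateau) <= tolerance * plateau
    if not within[0]:
        return LVERResult(
            strain_range=None,
            recommended_strain=None,
            plateau_modulus=plateau,
            n_points=0,
            diagnostic="no plateau: first point already deviates beyond tolerance",
        )
    end = int(np.argmin(within)) if not within.all() else len(within)
    lo = float(sweep.strain_amplitudes[0])
    hi = float(sweep.strain_amplitudes[end - 1])
    rec = float(10 ** ((np.log10(lo) + np.log10(hi)) / 2.0)) if lo > 0 else (lo + hi) / 2
    return LVERResult((lo, hi), rec, plateau, end)


def moduli_at_frequency(
    sweep: FrequencySweep, f: float, interpolation: str = "loglog"
) -> tuple[float, float]:
    """(G', G'') at frequency ``f``; exact at grid points, no extrapolation.

    Between grid points, log-log linear interpolation by default (moduli of
    collagen gels are near power-law in frequency); ``interpolation="linear"``
    interpolates on the raw scale.
    """
    fr = sweep.frequencies
    if f < fr[0] or f > fr[-1]:
        raise ValueError(f"frequency {f} Hz outside sweep range [{fr[0]}, {fr[-1]}]")
    exact = np.nonzero(np.isclose(fr, f, rtol=1e-12, atol=0.0))[0]
    if exact.size:
        i = int(exact[0])
        return float(sweep.storage_modulus[i]), float(sweep.loss_modulus[i])
    if interpolation == "loglog":
        lg = np.log(fr)
        gp = float(np.exp(np.interp(np.log(f), lg, np.log(sweep.storage_modulus))))
        gpp = float(np.exp(np.interp(np.log(f), lg, np.log(sweep.loss_modulus))))
    elif interpolation == "linear":
        gp = float(np.interp(f, fr, sweep.storage_modulus))
        gpp = float(np.interp(f, fr, sweep.loss_modulus))
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    return gp, gpp


def summary_from_moduli(
    g_prime: float,
    g_prime_sd: float,
    g_double_prime: float,
    g_double_prime_sd: float = 0.0,
    nu: float = 0.5,
    n_replicates: int = 1,
    frequency_hz: float = 1.0,
) -> RheologySummary:
    """Summary directly from (mean, sd) moduli, e.g. published values."""
    tan_delta = g_double_prime / g_prime
    e_prime = 2.0 * g_prime * (1.0 + nu)
    return RheologySummary(
        G_prime_1Hz=float(g_prime),
        G_prime_sd=float(g_prime_sd),
        G_double_prime_1Hz=float(g_double_prime),
        G_double_prime_sd=float(g_double_prime_sd),
        loss_tangent=float(tan_delta),
        poisson_ratio=float(nu),
        E_prime=float(e_prime),
        E_prime_sd=float(2.0 * (1.0 + nu) * g_prime_sd),
        n_replicates=n_replicates,
        frequency_hz=frequency_hz,
    )


def summarize(
    replicates: list[FrequencySweep], nu: float = 0.5, frequency: float = 1.0
) -> RheologySummary:
    """Mean ± sd 1 Hz moduli across replicates and the derived summaries.

    The sd is the sample standard deviation (ddof=1) across replicates, 0 for
    a single replicate. Invariant to replicate order.
    """
    if not replicates:
        raise ValueError("need at least one replicate sweep")
    vals = np.array([moduli_at_frequency(s, frequency) for s in replicates])
    gp, gpp = vals[:, 0], vals[:, 1]
    n = len(replicates)
    gp_sd = float(np.std(gp, ddof=1)) if n > 1 else 0.0
    gpp_sd = float(np.std(gpp, ddof=1)) if n > 1 else 0.0
    summary = summary_from_moduli(
        float(np.mean(gp)),
        gp_sd,
        float(np.mean(gpp)),
        gpp_sd,
        nu=nu,
        n_replicates=n,
        frequency_hz=frequency,
    )
    summary.per_replicate_loss_tangent = list(gpp / gp)
    return summary


# ---------------------------------------------------------------------------
# CSV I/O (columns: frequency_hz | strain_pct, g_prime_pa, g_double_prime_pa,
# replicate)
# ---------------------------------------------------------------------------


def read_frequency_sweeps(path) -> list[FrequencySweep]:
    df = pd.read_csv(path)
    required = {"frequency_hz", "g_prime_pa", "g_double_prime_pa"}
    if not required.issubset(df.columns):
        raise ValueError(f"CSV must have columns {sorted(required)}")
    if "replicate" not in df.columns:
        df["replicate"] = "r0"
    sweeps = []
    for rep, grp in df.groupby("replicate", sort=True):
        grp = grp.sort_values("frequency_hz")
        sweeps.append(
            FrequencySweep(
                grp["frequency_hz"].to_numpy(),
                grp["g_prime_pa"].to_numpy(),
                grp["g_double_prime_pa"].to_numpy(),
                replicate_id=str(rep),
            )
        )
    return sweeps


def read_strain_sweep(path) -> StrainSweep:
    df = pd.read_csv(path).sort_values("strain_pct")
    return StrainSweep(
        df["strain_pct"].to_numpy(),
        df["g_prime_pa"].to_numpy(),
        df["g_double_prime_pa"].to_numpy(),
    )
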