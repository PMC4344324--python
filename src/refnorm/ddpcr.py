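"""Absolute quantification from droplet digital PCR well counts.

A ddPCR reaction is partitioned into n droplets of volume v; molecules
land in droplets independently, so the number per droplet is Poisson with
mean lambda and the fraction of positive droplets estimates
``1 - exp(-lambda)``. Inverting,

    lambda = -ln(1 - k/n),        conc [copies/ul] = lambda / v

with v in microlitres. The 95% confidence interval uses the delta-method
standard error ``sigma_lambda = sqrt(k / (n (n - k)))``; a parametric
bootstrap serves as the validation oracle in the test suite.
Concentrations can be background-corrected against no-template-control
(NTC) wells and converted to copies per nanogram of cDNA input.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import DomainError, SaturationError

__all__ = [
    "poisson_lambda",
    "concentration",
    "confidence_interval95",
    "background_correct",
    "copies_per_ng",
    "quantify_wells",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


def poisson_lambda(k: int, n: int) -> float:
    """Mean copies per droplet from k positive out of n droplets."""
    if n <= 0 or k < 0 or k > n:
        raise DomainError(f"invalid droplet counts k={k}, n={n}")
    if k == n:
        raise SaturationError(
            "all droplets positive: concentration exceeds the quantifiable range"
        )
    return float(-np.log1p(-k / n))


def concentration(lam: float, droplet_volume: float) -> float:
    """Copies per microlitre of reaction from lambda and droplet volume (nL)."""
    if droplet_volume <= 0:
        raise DomainError("droplet volume must be positive")
    if lam < 0:
        raise DomainError("lambda must be >= 0")
    return lam / (droplet_volume * 1e-3)


def confidence_interval95(k: int, n: int, droplet_volume: float
                          ) -> tuple[float, float]:
    """Poisson 95% confidence interval on the concentration, copies/ul.

    For 0 < k < n the delta-method interval ``(lambda +/- 1.96 sigma)/v``
    is floored at 0. For k = 0 a one-sided interval is returned, with the
    rule-of-three bound 3/n mapped through the same transform.
    """
    if droplet_volume <= 0:
        raise DomainError("droplet volume must be positive")
    if k == 0:
        upper = -np.log1p(-3.0 / n)
        return 0.0, concentration(upper, droplet_volume)
    lam = poisson_lambda(k, n)  # validates counts, raises on saturation
    sigma = np.sqrt(k / (n * (n - k)))
    low = max(0.0, lam - _Z95 * sigma)
    high = lam + _Z95 * sigma
    return (concentration(low, droplet_volume),
            concentration(high, droplet_volume))


def background_correct(sample_conc: float, ntc_conc: float) -> float:
    """Subtract the mean NTC concentration, flooring at zero."""
    if sample_conc < 0 or ntc_conc < 0:
        raise DomainError("concentrations must be >= 0")
    return max(0.0, sample_conc - ntc_conc)


def copies_per_ng(conc: float, reaction_volume: float, cdna_input: float) -> float:
    """Convert copies/ul of reaction to copies per ng of cDNA input."""
    if cdna_input <= 0:
        raise DomainError("cdna_input must be positive")
    if reaction_volume <= 0:
        raise DomainError("reaction_volume must be positive")
    return conc * reaction_volume / cdna_input


def quantify_wells(
    wells: pd.DataFrame,
    droplet_volume: float = 0.85,
    reaction_volume: float = 20.0,
    background_correction: bool = True,
) -> pd.DataFrame:
    """Quantify every non-NTC well of a droplet table.

    Parameters
    ----------
    wells : DataFrame
        Columns ``well``, ``target``, ``sample``, ``n_total``,
        ``n_positive``, ``is_ntc``; optional ``day``, ``replicate`` and
        ``cdna_input`` (ng) columns are carried through / used.
    droplet_volume : float
        Droplet volume in nL (instrument convention; default 0.85).
    background_correction : bool
        Subtract, per target, the mean concentration of that target's NTC
        wells. Targets without an NTC well get a warning and no correction.

    Returns
    -------
    DataFrame with ``lambda``, ``conc``, ``ci_low``, ``ci_high``,
    ``conc_bg`` and, when ``cdna_input`` is present, ``copies_per_ng``.
    """
    required = {"well", "target", "sample", "n_total", "n_positive", "is_ntc"}
    missing = required - set(wells.columns)
    if missing:
        raise DomainError(f"droplet table lacks columns: {sorted(missing)}")

    lam = np.array([poisson_lambda(k, n) for k, n in
                    zip(wells["n_positive"], wells["n_total"])])
    conc = lam / (droplet_volume * 1e-3)
    all_quant = wells.assign(**{"lambda": lam, "conc": conc})

    ntc = all_quant[all_quant["is_ntc"]]
    ntc_mean = ntc.groupby("target")["conc"].mean()

    out = all_quant[~all_quant["is_ntc"]].copy()
    ci = [confidence_interval95(k, n, droplet_volume)
          for k, n in zip(out["n_positive"], out["n_total"])]
    out["ci_low"] = [c[0] for c in ci]
    out["ci_high"] = [c[1] for c in ci]

    if background_correction:
        bg = out["target"].map(ntc_mean)
        no_ntc = bg.isna()
        if no_ntc.any():
            warnings.warn(
                "no NTC well for target(s) "
                f"{sorted(out.loc[no_ntc, 'target'].unique())}; "
                "left uncorrected",
                stacklevel=2,
            )
        out["conc_bg"] = np.maximum(0.0, out["conc"] - bg.fillna(0.0))
    else:
        out["conc_bg"] = out["conc"]

    if "cdna_input" in out.columns and out["cdna_input"].notna().all():
        out["copies_per_ng"] = out["conc_bg"] * reaction_volume / out["cdna_input"]
    return out.reset_index(drop=True)
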