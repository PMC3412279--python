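"""Brain-wise association study (BWAS) over binarized individual networks.

Each subject's connectivity matrix is reduced to a binary network recording
which links "exist". For every link, the proportions of controls (rho_H) and
patients (rho_P) carrying it estimate the group occurrence probabilities;
the score S = rho_H - rho_P is tested against zero with a normal
approximation to the difference of two binomial proportions:

    sigma^2 = rho_H (1 - rho_H) / N_H + rho_P (1 - rho_P) / N_P
    p       = Phi(-|S| / sigma)

Links whose occurrence is near-universal or near-absent in BOTH groups
(both proportions < 0.02 or both > 0.98) are excluded before testing — the
normal approximation is invalid there and they carry no group contrast.
Benjamini-Hochberg FDR correction is applied over the retained links.

The one-tailed Phi(-|S|/sigma) form applied to an absolute score rejects a
true null at twice the nominal rate; a conventional doubled (two-sided)
p-value is available via ``p_convention="two_sided"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .connectivity import ConnectivityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "BWASConfig",
    "BinaryNetworkSet",
    "bwas_threshold",
    "binarize_networks",
    "link_counts",
    "bwas_test",
    "run_bwas",
]


@dataclass(frozen=True)
class BWASConfig:
    """Proportion filter, p-value convention and FDR level.

    ``p_convention="as_printed"`` uses p = Phi(-|S|/sigma); ``"two_sided"``
    doubles it. ``alpha`` is the per-link significance level for raw-p
    thresholding; ``fdr_q`` the Benjamini-Hochberg level.
    """

    prop_floor: float = 0.02
    prop_ceiling: float = 0.98
    alpha: float = 0.05
    p_convention: str = "as_printed"
    fdr_q: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.prop_floor < self.prop_ceiling < 1:
            raise ValueError("require 0 < prop_floor < prop_ceiling < 1")
        if self.p_convention not in ("as_printed", "two_sided"):
            raise ValueError("p_convention must be 'as_printed' or 'two_sided'")


@dataclass
class BinaryNetworkSet:
    """Per-subject link presence: (n_subjects, n_links) boolean array over
    upper-triangle links, plus per-subject group labels."""

    presence: np.ndarray  # (n_subjects, n_links) bool
    labels: np.ndarray  # (n_subjects,) "control" | "patient"
    n_regions: int

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        self.labels = np.asarray(self.labels)
        n_links = self.n_regions * (self.n_regions - 1) // 2
        if self.presence.shape != (self.labels.size, n_links):
            raise ValueError("presence shape does not match labels/regions")


def binarize_networks(
    matrices: list[ConnectivityMatrix],
    labels: np.ndarray,
    rule: str = "significance",
    *,
    n_timepoints: int | None = None,
    n_effective: int | None = None,
    edge_alpha: float = 0.05,
    abs_threshold: float = 0.2,
    density: float = 0.1,
) -> BinaryNetworkSet:
    """Reduce each subject's connectivity matrix to link presence/absence.

    Rules
    -----
    ``"significance"`` (default): a link exists when the subject-level
    correlation is significantly nonzero at ``edge_alpha`` under the
    t-transform t = rho sqrt(df) / sqrt(1 - rho^2) with df = T - n (each of
    the n - 2 conditioning regions plus the two means costs one degree of
    freedom). Requires ``n_timepoints``. For temporally autocorrelated
    (e.g. bandpass-filtered) series, pass ``n_effective`` — the effective
    number of independent samples, roughly T x bandwidth / Nyquist for an
    ideally bandlimited process — which replaces T in the df; otherwise the
    test is sharply anticonservative.

    ``"absolute"``: |rho| > abs_threshold.

    ``"proportional"``: the floor(density * n_links) strongest |rho| links
    per subject.
    """
    if not matrices:
        raise ValueError("no matrices given")
    n = matrices[0].region_count
    vals = np.stack([m.upper_values() for m in matrices])  # (subjects, links)
    if rule == "significance":
        if n_timepoints is None and n_effective is None:
            raise ValueError("significance rule needs n_timepoints or n_effective")
        df = (n_effective if n_effective is not None else n_timepoints) - n
        if df <= 0:
            raise ValueError(
                f"df = T - n = {df} <= 0; use shrinkage upstream or the "
                "'absolute' rule"
            )
        rho = np.clip(vals, -0.999999, 0.999999)
        t = rho * np.sqrt(df) / np.sqrt(1.0 - rho**2)
        p = 2.0 * stats.t.sf(np.abs(t), df)
        presence = p < edge_alpha
    elif rule == "absolute":
        presence = np.abs(vals) > abs_threshold
    elif rule == "proportional":
        n_links = vals.shape[1]
        k = int(np.floor(density * n_links))
        presence = np.zeros_like(vals, dtype=bool)
        if k > 0:
            order = np.argsort(-np.abs(vals), axis=1)[:, :k]
            np.put_along_axis(presence, order, True, axis=1)
    else:
        raise ValueError(f"unknown binarization rule {rule!r}")
    return BinaryNetworkSet(presence=presence, labels=np.asarray(labels), n_regions=n)


def link_counts(nets: BinaryNetworkSet) -> pd.DataFrame:
    """Per-link tallies L_H, L_P and group sizes N_H, N_P."""
    is_control = nets.labels == "control"
    is_patient = nets.labels == "patient"
    if not is_control.any() or not is_patient.any():
        raise ValueError("both groups must be nonempty")
    iu = np.triu_indices(nets.n_regions, k=1)
    return pd.DataFrame(
        {
            "region_i": iu[0],
            "region_j": iu[1],
            "L_H": nets.presence[is_control].sum(axis=0),
            "L_P": nets.presence[is_patient].sum(axis=0),
            "N_H": int(is_control.sum()),
            "N_P": int(is_patient.sum()),
        }
    )


def bwas_test(counts: pd.DataFrame, config: BWASConfig = BWASConfig()) -> pd.DataFrame:
    """Two-proportion occurrence test per link.

    Adds rho_H, rho_P, S_hat, sigma_hat, p_value, retained to the counts
    table. ``retained`` is False for links failing the proportion filter
    (both proportions below the floor or both above the ceiling). Degenerate
    links with sigma_hat = 0 get p = 1 when S_hat = 0 and p = 0 (the limit)
    otherwise, with a warning.
    """
    out = counts.copy()
    rho_H = out["L_H"] / out["N_H"]
    rho_P = out["L_P"] / out["N_P"]
    S = rho_H - rho_P
    var = rho_H * (1 - rho_H) / out["N_H"] + rho_P * (1 - rho_P) / out["N_P"]
    sigma = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, np.abs(S) / sigma, np.inf)
    p = stats.norm.cdf(-z)
    p = np.where((sigma == 0) & (S == 0), 1.0, p)
    if np.any((sigma.values == 0) & (S.values != 0)):
        logger.warning(
            "links with sigma_hat = 0 but S_hat != 0: p set to the 0 limit"
        )
    if config.p_convention == "two_sided":
        p = np.minimum(2.0 * p, 1.0)
    floor, ceil = config.prop_floor, config.prop_ceiling
    retained = ~(((rho_H < floor) & (rho_P < floor)) | ((rho_H > ceil) & (rho_P > ceil)))
    out["rho_H"] = rho_H
    out["rho_P"] = rho_P
    out["S_hat"] = S
    out["sigma_hat"] = sigma
    out["p_value"] = p
    out["retained"] = retained
    return out


def bwas_threshold(sigma_hat: float, alpha: float) -> float:
    """Score magnitude needed for alpha-level significance: -sigma * Phi^-1(alpha)."""
    if not 0 < alpha < 0.5:
        raise ValueError(f"alpha must be in (0, 0.5), got {alpha}")
    return float(-sigma_hat * stats.norm.ppf(alpha))


def fdr_correct(result: pd.DataFrame, q: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg step-up over retained links only.

    Adds ``q_value`` (NaN for filtered-out links) and ``significant``.
    """
    out = result.copy()
    out["q_value"] = np.nan
    out["significant"] = False
    mask = out["retained"].to_numpy()
    if not mask.any():
        logger.warning("no links retained: FDR correction skipped")
        return out
    rej, qvals, *_ = multipletests(
        out.loc[mask, "p_value"].to_numpy(), alpha=q, method="fdr_bh"
    )
    out.loc[mask, "q_value"] = qvals
    out.loc[mask, "significant"] = rej
    return out


def run_bwas(
    nets: BinaryNetworkSet, config: BWASConfig = BWASConfig()
) -> pd.DataFrame:
    """Counts -> proportion tests -> FDR, in one table."""
    return fdr_correct(bwas_test(link_counts(nets), config), q=config.fdr_q)
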