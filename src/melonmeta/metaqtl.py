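"""Two-step consensus analysis of co-located QTLs.

Step 1 models the observed positions within one trait x chromosome group as a
K-component Gaussian mixture in which every observation keeps its own known
variance (derived from its confidence-interval width); K is chosen by AIC.
Step 2 collapses each component to a consensus position by inverse-variance
weighting of its members, with a 95% interval of +/- 1.96 consensus sd.

Positions are in Mb on the projected physical reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .projection import ProjectedQTL, chrom_number
from .qtl_io import ChromosomeTable, QTLRecord

__all__ = [
    "Z95",
    "GaussianObservation",
    "MixtureModel",
    "MetaQTL",
    "MetaConfig",
    "ci_to_sd",
    "mixture_loglik",
    "fit_em",
    "select_K",
    "map_assign",
    "consensus",
    "build_observations",
    "run_metaqtl",
]

Z95 = 1.96  # conventional 95% normal quantile; CI width = 3.92 sd
_LOG_2PI = math.log(2.0 * math.pi)
DEFAULT_SD_MIN_MB = 0.01


@dataclass(frozen=True)
class GaussianObservation:
    """A projected QTL reduced to (position, sd) in Mb for the mixture model."""

    qtl_id: str
    position: float
    sd: float
    lod: Optional[float] = None
    pve_percent: Optional[float] = None
    sd_imputed: bool = False

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError(f"sd must be positive, got {self.sd}")


@dataclass(frozen=True)
class MixtureModel:
    """A fitted known-variance Gaussian mixture with its AIC bookkeeping."""

    K: int
    means: tuple[float, ...]
    proportions: tuple[float, ...]
    log_likelihood: float
    n_free_params: int
    aic: float
    converged: bool
    n_iter: int
    seed: int
    aic_trace: tuple[tuple[int, float], ...] = ()


@dataclass(frozen=True)
class MetaQTL:
    """A consensus locus combining member QTLs of one mixture component."""

    mqtl_id: str
    trait_code: str
    chrom: str
    member_ids: tuple[str, ...]
    consensus_position: float
    consensus_sd: float
    ci95_start: float
    ci95_end: float
    model_K: int
    model_aic: float
    singleton: bool = False


@dataclass
class MetaConfig:
    k_max: int = 5
    min_members: int = 2
    sd_min_mb: float = DEFAULT_SD_MIN_MB
    n_restarts: int = 10
    tol: float = 1e-8
    max_iter: int = 500
    seed: int = 17
    drop_singletons: bool = False


def ci_to_sd(ci_width: float, coverage: float = 0.95, sd_min: float = DEFAULT_SD_MIN_MB) -> float:
    """Convert a confidence-interval width to the implied Gaussian sd.

    sd = width / (2 z), with z the (1+coverage)/2 normal quantile; for 95%
    this is width / 3.92.  The result is floored at ``sd_min`` so zero-width
    literature intervals cannot produce infinite weights.
    """
    if ci_width <= 0:
        raise ValueError(f"ci_width must be positive, got {ci_width}")
    if coverage == 0.95:
        z = Z95
    else:
        from scipy.stats import norm

        z = float(norm.ppf((1.0 + coverage) / 2.0))
    return max(ci_width / (2.0 * z), sd_min)


def _arrays(obs: Sequence[GaussianObservation]) -> tuple[np.ndarray, np.ndarray]:
    x = np.array([o.position for o in obs], dtype=float)
    s = np.array([o.sd for o in obs], dtype=float)
    return x, s


def _log_density_matrix(x: np.ndarray, s: np.ndarray, means: np.ndarray) -> np.ndarray:
    """log phi(x_i; mu_k, s_i^2) as an (n, K) matrix; variance is per-observation."""
    z = (x[:, None] - means[None, :]) / s[:, None]
    return -0.5 * _LOG_2PI - np.log(s)[:, None] - 0.5 * z * z


def mixture_loglik(
    obs: Sequence[GaussianObservation],
    means: Sequence[float],
    proportions: Sequence[float],
) -> float:
    """Mixture log-likelihood; components share each observation's own variance.

    logL = sum_i log sum_k pi_k phi(x_i; mu_k, sd_i^2), evaluated with
    log-sum-exp stability.
    """
    means = np.asarray(means, dtype=float)
    proportions = np.asarray(proportions, dtype=float)
    if means.shape != proportions.shape or means.ndim != 1 or means.size < 1:
        raise ValueError("means and proportions must be equal-length 1-D, K >= 1")
    if not math.isclose(float(proportions.sum()), 1.0, abs_tol=1e-8):
        raise ValueError("proportions must sum to 1")
    x, s = _arrays(obs)
    logp = _log_density_matrix(x, s, means) + np.log(proportions)[None, :]
    return float(logsumexp(logp, axis=1).sum())


def _aic(loglik: float, K: int) -> float:
    return -2.0 * loglik + 2.0 * (2 * K - 1)


def _ivw_mean(x: np.ndarray, s: np.ndarray) -> float:
    w = 1.0 / (s * s)
    return float((w * x).sum() / w.sum())


def _em_once(
    x: np.ndarray,
    s: np.ndarray,
    mu0: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, float, bool, int]:
    K = mu0.size
    mu = mu0.astype(float).copy()
    pi = np.full(K, 1.0 / K)
    prev = -np.inf
    ll = prev
    converged = False
    it = 0
    inv_var = 1.0 / (s * s)
    for it in range(1, max_iter + 1):
        logp = _log_density_matrix(x, s, mu) + np.log(pi)[None, :]
        norm = logsumexp(logp, axis=1)
        ll = float(norm.sum())
        # EM guarantees monotone logL; tolerate only float round-off
        assert ll >= prev - 1e-7 * max(1.0, abs(prev)), "log-likelihood decreased"
        if abs(ll - prev) < tol:
            converged = True
            break
        prev = ll
        resp = np.exp(logp - norm[:, None])
        w = resp * inv_var[:, None]
        denom = np.maximum(w.sum(axis=0), 1e-300)
        mu = (w * x[:, None]).sum(axis=0) / denom
        pi = np.clip(resp.mean(axis=0), 1e-12, None)
        pi = pi / pi.sum()
    return mu, pi, ll, converged, it


def fit_em(
    obs: Sequence[GaussianObservation],
    K: int,
    n_restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 17,
) -> MixtureModel:
    """Fit a K-component known-variance mixture by EM with restarts.

    The first restart uses deterministic quantile initialization of the means;
    the remaining restarts draw K observed positions (with jitter) from a
    generator seeded by (seed, K, restart).  K = 1 bypasses EM: the maximum
    likelihood mean is the closed-form inverse-variance-weighted mean.
    """
    n = len(obs)
    if K < 1:
        raise ValueError("K must be >= 1")
    if n < K:
        raise ValueError("K exceeds observations")
    x, s = _arrays(obs)
    if K == 1:
        mu = np.array([_ivw_mean(x, s)])
        pi = np.array([1.0])
        ll = mixture_loglik(obs, mu, pi)
        return MixtureModel(
            K=1,
            means=(float(mu[0]),),
            proportions=(1.0,),
            log_likelihood=ll,
            n_free_params=1,
            aic=_aic(ll, 1),
            converged=True,
            n_iter=0,
            seed=seed,
        )
    spread = float(np.std(x))
    best: Optional[tuple] = None
    for r in range(max(1, n_restarts)):
        if r == 0:
            mu0 = np.quantile(x, (2.0 * np.arange(K) + 1.0) / (2.0 * K))
        else:
            rng = np.random.default_rng([seed, K, r])
            mu0 = rng.choice(x, size=K, replace=n < K)
            mu0 = mu0 + rng.normal(0.0, 0.05 * spread + 1e-9, size=K)
        mu, pi, ll, converged, it = _em_once(x, s, mu0, tol, max_iter)
        if best is None or ll > best[2]:
            best = (mu, pi, ll, converged, it)
    mu, pi, ll, converged, it = best
    order = np.argsort(mu)
    mu, pi = mu[order], pi[order]
    return MixtureModel(
        K=K,
        means=tuple(float(v) for v in mu),
        proportions=tuple(float(v) for v in pi),
        log_likelihood=ll,
        n_free_params=2 * K - 1,
        aic=_aic(ll, K),
        converged=converged,
        n_iter=it,
        seed=seed,
    )


def select_K(
    obs: Sequence[GaussianObservation],
    K_max: int,
    n_restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 17,
) -> MixtureModel:
    """Fit K = 1..K_max and return the lowest-AIC model (ties -> smaller K).

    K_max is capped at the number of observations; the full AIC trace is
    attached to the returned model for reporting.
    """
    n = len(obs)
    if n == 0:
        raise ValueError("no observations")
    K_max = min(K_max, n)
    best: Optional[MixtureModel] = None
    trace: list[tuple[int, float]] = []
    for K in range(1, K_max + 1):
        model = fit_em(obs, K, n_restarts=n_restarts, tol=tol, max_iter=max_iter, seed=seed)
        trace.append((K, model.aic))
        if best is None or model.aic < best.aic:
            best = model
    return MixtureModel(**{**best.__dict__, "aic_trace": tuple(trace)})


def map_assign(obs: Sequence[GaussianObservation], model: MixtureModel) -> np.ndarray:
    """Maximum-a-posteriori component label per observation (ties -> lower k)."""
    x, s = _arrays(obs)
    logp = _log_density_matrix(x, s, np.asarray(model.means)) + np.log(
        np.asarray(model.proportions)
    )
    return np.argmax(logp, axis=1)


def consensus(
    members: Sequence[GaussianObservation],
) -> tuple[float, float, tuple[float, float]]:
    """Inverse-variance-weighted consensus of one component's members.

    position = sum(x_i / sd_i^2) / sum(1 / sd_i^2); sd = sqrt of the inverse
    total weight (never larger than the smallest member sd); the 95% interval
    is position +/- 1.96 sd.
    """
    if not members:
        raise ValueError("consensus of empty member list")
    x, s = _arrays(members)
    w = 1.0 / (s * s)
    pos = float((w * x).sum() / w.sum())
    sd = float(math.sqrt(1.0 / w.sum()))
    return pos, sd, (pos - Z95 * sd, pos + Z95 * sd)


def _peak_fraction(rec: QTLRecord) -> float:
    """Position of the genetic peak inside its CI as a fraction (0.5 default)."""
    if rec.peak_cM is None:
        return 0.5
    width = rec.ci_end_cM - rec.ci_start_cM
    if width <= 0:
        return 0.5
    return (rec.peak_cM - rec.ci_start_cM) / width


def build_observations(
    records: Sequence[ProjectedQTL],
    qtl_by_id: Mapping[str, QTLRecord],
    sd_min_mb: float = DEFAULT_SD_MIN_MB,
) -> dict[tuple[str, str], list[GaussianObservation]]:
    """Turn retained projected QTLs into per-(trait, chromosome) observations.

    The position is the physical peak (genetic peak interpolated into the
    projected interval) or the interval midpoint when no peak is reported; the
    sd comes from the projected interval width via ``ci_to_sd``.  Records
    whose projected width is degenerate get the group's median width instead
    and are flagged ``sd_imputed``.
    """
    groups: dict[tuple[str, str], list[ProjectedQTL]] = {}
    for rec in records:
        if rec.is_retained:
            groups.setdefault((rec.trait_code, rec.chrom), []).append(rec)
    out: dict[tuple[str, str], list[GaussianObservation]] = {}
    for key, members in groups.items():
        widths = [m.length_bp / 1e6 for m in members if m.length_bp and m.length_bp > 0]
        median_width = float(np.median(widths)) if widths else 4.0 * sd_min_mb
        obs = []
        for m in sorted(members, key=lambda r: (r.start_bp, r.qtl_id)):
            qtl = qtl_by_id[m.qtl_id]
            start_mb, end_mb = m.start_bp / 1e6, m.end_bp / 1e6
            width = end_mb - start_mb
            imputed = width <= 0
            if imputed:
                width = median_width
            pos = start_mb + _peak_fraction(qtl) * (end_mb - start_mb)
            obs.append(
                GaussianObservation(
                    qtl_id=m.qtl_id,
                    position=pos,
                    sd=ci_to_sd(width, sd_min=sd_min_mb),
                    lod=qtl.lod,
                    pve_percent=qtl.pve_percent,
                    sd_imputed=imputed,
                )
            )
        out[key] = obs
    return out


def run_metaqtl(
    records: Sequence[ProjectedQTL],
    qtl_by_id: Mapping[str, QTLRecord],
    chroms: ChromosomeTable,
    config: Optional[MetaConfig] = None,
) -> tuple[list[MetaQTL], dict[tuple[str, str], MixtureModel]]:
    """Full two-step consensus analysis over every trait x chromosome group.

    Groups with fewer than ``min_members`` observations are skipped (a single
    mapping is not meta-evidence).  Per group: select K by AIC, MAP-assign
    members, collapse each non-empty component by inverse-variance consensus,
    and name the results ``MQTL-<trait><chrom#>.<rank>`` by ascending
    position.  One-member components are flagged as singletons (dropped only
    when the config says so).

    Returns the meta-QTLs plus the selected model per group.
    """
    config = config or MetaConfig()
    observations = build_observations(records, qtl_by_id, sd_min_mb=config.sd_min_mb)
    mqtls: list[MetaQTL] = []
    models: dict[tuple[str, str], MixtureModel] = {}
    for trait, chrom in sorted(observations):
        obs = observations[(trait, chrom)]
        if len(obs) < config.min_members:
            continue
        model = select_K(
            obs,
            config.k_max,
            n_restarts=config.n_restarts,
            tol=config.tol,
            max_iter=config.max_iter,
            seed=config.seed,
        )
        models[(trait, chrom)] = model
        labels = map_assign(obs, model)
        chrom_mb = chroms[chrom] / 1e6
        components = []
        for k in range(model.K):
            members = [o for o, lab in zip(obs, labels) if lab == k]
            if not members:
                continue
            if len(members) == 1 and config.drop_singletons:
                continue
            pos, sd, (lo, hi) = consensus(members)
            components.append((pos, sd, lo, hi, members))
        components.sort(key=lambda c: c[0])
        for rank, (pos, sd, lo, hi, members) in enumerate(components, start=1):
            mqtls.append(
                MetaQTL(
                    mqtl_id=f"MQTL-{trait}{chrom_number(chrom)}.{rank}",
                    trait_code=trait,
                    chrom=chrom,
                    member_ids=tuple(o.qtl_id for o in members),
                    consensus_position=pos,
                    consensus_sd=sd,
                    ci95_start=max(0.0, lo),
                    ci95_end=min(chrom_mb, hi),
                    model_K=model.K,
                    model_aic=model.aic,
                    singleton=len(members) == 1,
                )
            )
    return mqtls, models
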