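"""Regularized Poisson text scaling (Wordfish-class).

The model places document i at position θ_i on a latent semantic
dimension and gives word j a loading β_j on that dimension:

    y_ij ~ Poisson(μ_ij),   log μ_ij = α_i + ψ_j + β_j · θ_i

with α_i a document verbosity intercept and ψ_j a word frequency
intercept.  Ridge penalties λ_β·Σβ² and λ_θ·Σθ² stabilize the estimates
on short documents, where unpenalized scaling is notoriously noisy.

Estimation alternates penalized Poisson-likelihood maximization:

* word step — for each word j, a damped Newton update of (ψ_j, β_j)
  given θ, α;
* document step — for each document i, a damped Newton update of
  (α_i, θ_i) given ψ, β;
* after each sweep θ is re-centered, the shift absorbed into ψ so the
  fitted rates are unchanged.  Each half-step uses step-halving, so the
  penalized log-likelihood is non-decreasing along the trace.

The latent dimension is identified only up to location/scale/sign: after
convergence θ is standardized to mean 0, SD 1 (with compensating
transforms of ψ and β, leaving all fitted rates untouched), and the sign
is fixed separately by anchoring on a mind/brain lexicon
(:func:`orient_dimension`), so the positive end reads as mind/brain.

Initialization is deterministic: θ starts at the first principal
component of the row-standardized log(1+count) matrix, ψ at log mean
word counts, α at log relative document lengths; ``seed`` only adds
optional jitter and is irrelevant at the default ``jitter=0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .corpus import DocumentTermMatrix
from .inference import EffectSize, hedges_g
from .lexicon import Lexicon


@dataclass
class ScalingFit:
    doc_ids: list[str]
    vocab: list[str]
    theta: np.ndarray
    alpha: np.ndarray
    psi: np.ndarray
    beta: np.ndarray
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    lambda_beta: float
    lambda_theta: float
    oriented: bool = False

    def loading_table(self):
        import pandas as pd

        return pd.DataFrame({"stem": self.vocab, "beta": self.beta, "psi": self.psi})

    def position_table(self):
        import pandas as pd

        return pd.DataFrame({"doc_id": self.doc_ids, "theta": self.theta, "alpha": self.alpha})


def _penalized_loglik(Y, alpha, psi, beta, theta, lam_b, lam_t) -> float:
    eta = alpha[:, None] + psi[None, :] + np.outer(theta, beta)
    # log y! dropped: constant in the parameters
    return float(np.sum(Y * eta - np.exp(eta)) - lam_b * beta @ beta - lam_t * theta @ theta)


def _newton_pair(Y, alpha, psi, beta, theta, lam, axis: str):
    """One damped Newton update of all (ψ_j, β_j) pairs (axis="word") or
    all (α_i, θ_i) pairs (axis="doc"), vectorized across the axis.

    Returns updated parameter arrays; step-halving per element guarantees
    each pair's penalized objective contribution does not decrease.
    """
    if axis == "word":
        # intercept = psi (per word), slope = beta (per word), carrier = theta
        carrier, inter, slope = theta, psi.copy(), beta.copy()
        Yax = Y  # docs x words; sums over axis 0
        off = alpha
        sum_ax = 0
    else:
        carrier, inter, slope = beta, alpha.copy(), theta.copy()
        Yax = Y.T  # words x docs; sums over axis 0
        off = psi
        sum_ax = 0

    def objective(inter_v, slope_v):
        eta = off[:, None] + inter_v[None, :] + carrier[:, None] * slope_v[None, :]
        return np.sum(Yax * eta - np.exp(eta), axis=sum_ax) - lam * slope_v**2

    f0 = objective(inter, slope)
    eta = off[:, None] + inter[None, :] + carrier[:, None] * slope[None, :]
    mu = np.exp(eta)
    resid = Yax - mu
    g1 = resid.sum(axis=0)
    g2 = carrier @ resid - 2.0 * lam * slope
    h11 = mu.sum(axis=0)
    h12 = carrier @ mu
    h22 = (carrier**2) @ mu + 2.0 * lam
    det = h11 * h22 - h12 * h12
    det = np.where(det <= 1e-12, 1e-12, det)
    step_inter = (h22 * g1 - h12 * g2) / det
    step_slope = (h11 * g2 - h12 * g1) / det

    scale = np.ones_like(inter)
    for _ in range(25):
        new_inter = inter + scale * step_inter
        new_slope = slope + scale * step_slope
        f1 = objective(new_inter, new_slope)
        bad = f1 < f0 - 1e-12
        if not bad.any():
            return new_inter, new_slope
        scale = np.where(bad, scale * 0.5, scale)
        keep = ~bad
        inter = np.where(keep, new_inter, inter)
        slope = np.where(keep, new_slope, slope)
        step_inter = np.where(keep, 0.0, step_inter)
        step_slope = np.where(keep, 0.0, step_slope)
        f0 = np.where(keep, f1, f0)
    return inter, slope


def fit_scaling(
    dtm: DocumentTermMatrix,
    lambda_beta: float = 0.1,
    lambda_theta: float = 0.1,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | None = None,
    jitter: float = 0.0,
    newton_steps: int = 3,
) -> ScalingFit:
    """Fit the penalized Poisson scaling model to a document-term matrix.

    Requires ≥2 documents, ≥2 words, and no all-zero row or column
    (guaranteed by :func:`painattrib.corpus.build_dtm`).  Stops when the
    relative change of the penalized log-likelihood falls below ``tol``;
    a fit that exhausts ``max_iter`` is returned with
    ``converged=False``.
    """
    Y = dtm.dense().astype(float)
    n, m = Y.shape
    if n < 2 or m < 2:
        raise ValueError("scaling needs at least 2 documents and 2 words")
    rowsum = Y.sum(axis=1)
    colsum = Y.sum(axis=0)
    if (rowsum == 0).any() or (colsum == 0).any():
        raise ValueError("degenerate DTM: all-zero document row or vocabulary column")
    if lambda_beta < 0 or lambda_theta < 0:
        raise ValueError("penalty weights must be >= 0")

    # Deterministic initialization
    alpha = np.log(rowsum) - np.mean(np.log(rowsum))
    psi = np.log(colsum / n)
    L = np.log1p(Y)
    Lc = L - L.mean(axis=0, keepdims=True)
    sd = L.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    Lc = Lc / sd
    # first left singular vector = first PC score direction
    u, s, _ = np.linalg.svd(Lc, full_matrices=False)
    theta = u[:, 0] * s[0]
    tsd = theta.std()
    theta = (theta - theta.mean()) / (tsd if tsd > 0 else 1.0)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        theta = theta + jitter * rng.standard_normal(n)
    beta = np.zeros(m)

    trace = [_penalized_loglik(Y, alpha, psi, beta, theta, lambda_beta, lambda_theta)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for _ in range(newton_steps):
            psi, beta = _newton_pair(Y, alpha, psi, beta, theta, lambda_beta, "word")
        for _ in range(newton_steps):
            alpha, theta = _newton_pair(Y, alpha, psi, beta, theta, lambda_theta, "doc")
        # Re-center θ each sweep; the shift is absorbed into ψ so fitted
        # rates are unchanged and the θ penalty can only decrease.
        mshift = theta.mean()
        theta = theta - mshift
        psi = psi + beta * mshift
        # Rebalance the β/θ scale indeterminacy: β→cβ, θ→θ/c leaves every
        # fitted rate unchanged; c is chosen to minimize the total ridge
        # penalty, so this is a monotone step that removes the slow drift
        # the alternating updates would otherwise take along this direction.
        if lambda_beta > 0 and lambda_theta > 0:
            ss_b, ss_t = float(beta @ beta), float(theta @ theta)
            if ss_b > 0 and ss_t > 0:
                c = (lambda_theta * ss_t / (lambda_beta * ss_b)) ** 0.25
                beta = beta * c
                theta = theta / c
        ll = _penalized_loglik(Y, alpha, psi, beta, theta, lambda_beta, lambda_theta)
        trace.append(ll)
        denom = abs(trace[-2]) if trace[-2] != 0 else 1.0
        if abs(ll - trace[-2]) / denom < tol:
            converged = True
            break

    # Final identification: θ to mean 0, SD 1 with compensating transforms
    # of ψ and β (all fitted rates unchanged).
    mshift = theta.mean()
    scale = theta.std()
    if scale > 0:
        theta = (theta - mshift) / scale
        psi = psi + beta * mshift
        beta = beta * scale

    return ScalingFit(
        doc_ids=list(dtm.doc_ids),
        vocab=list(dtm.vocab),
        theta=theta,
        alpha=alpha,
        psi=psi,
        beta=beta,
        loglik_trace=np.asarray(trace),
        converged=converged,
        n_iter=it,
        lambda_beta=lambda_beta,
        lambda_theta=lambda_theta,
    )


def orient_dimension(fit: ScalingFit, lexicon: Lexicon) -> ScalingFit:
    """Fix the global sign so the mind/brain end of the dimension is positive.

    The mean loading over lexicon stems present in the vocabulary decides
    the sign; if it is negative, θ and β are jointly negated (the model
    is invariant to this).  Idempotent.  If no lexicon stem is in the
    vocabulary the fit is returned unchanged with a warning.
    """
    import warnings

    mask = np.array([v in lexicon.stems for v in fit.vocab])
    if not mask.any():
        warnings.warn("no lexicon stem in vocabulary; orientation left unchanged",
                      stacklevel=2)
        return fit
    if fit.beta[mask].mean() < 0:
        fit = ScalingFit(
            doc_ids=fit.doc_ids, vocab=fit.vocab, theta=-fit.theta, alpha=fit.alpha,
            psi=fit.psi, beta=-fit.beta, loglik_trace=fit.loglik_trace,
            converged=fit.converged, n_iter=fit.n_iter,
            lambda_beta=fit.lambda_beta, lambda_theta=fit.lambda_theta, oriented=True,
        )
    else:
        fit.oriented = True
    return fit


@dataclass(frozen=True)
class GroupDifference:
    effect: EffectSize
    z: float
    p: float
    n1: int
    n2: int

    def to_dict(self) -> dict:
        return {"g": self.effect.g, "g_ci_low": self.effect.ci_low,
                "g_ci_high": self.effect.ci_high, "z": self.z, "p": self.p,
                "n1": self.n1, "n2": self.n2}


def rank_sum_z(x, y) -> tuple[float, float]:
    """Wilcoxon rank-sum Z via the normal approximation.

    Midranks for ties, tie-corrected variance, continuity correction of
    1/2 toward the null mean.  Positive Z means x tends larger than y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    w = ranks[:n1].sum()  # rank sum of x
    mu = n1 * (n1 + n2 + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)
    nt = n1 + n2
    var = n1 * n2 / 12.0 * ((nt + 1) - tie_term / (nt * (nt - 1)))
    if var == 0:
        return 0.0, 1.0
    diff = w - mu
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / np.sqrt(var)
    p = 2.0 * scipy.stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def position_group_difference(theta_a, theta_b) -> GroupDifference:
    """Hedges g and rank-sum test on document positions of two groups."""
    theta_a = np.asarray(theta_a, dtype=float)
    theta_b = np.asarray(theta_b, dtype=float)
    if len(theta_a) == 0 or len(theta_b) == 0:
        raise ValueError("both groups must be non-empty")
    z, p = rank_sum_z(theta_a, theta_b)
    if len(theta_a) < 2 or len(theta_b) < 2:
        raise ValueError("need at least 2 documents per group for an effect size")
    eff = hedges_g(theta_a, theta_b)
    return GroupDifference(effect=eff, z=z, p=p, n1=len(theta_a), n2=len(theta_b))


def simulate_scaling_dtm(
    n_docs: int = 100,
    n_words: int = 50,
    doc_length: float = 30.0,
    beta_sd: float = 0.7,
    seed: int = 0,
) -> tuple[DocumentTermMatrix, np.ndarray, np.ndarray]:
    """Draw a DTM from the Poisson scaling model with known θ*, β*.

    Used for parameter-recovery checks: returns (dtm, theta_star,
    beta_star) with θ* standardized.  Word intercepts are set so the
    expected document length is roughly ``doc_length`` tokens.
    """
    import pandas as pd
    import scipy.sparse as sp

    rng = np.random.default_rng(seed)
    theta = rng.standard_normal(n_docs)
    theta = (theta - theta.mean()) / theta.std()
    beta = rng.normal(0.0, beta_sd, size=n_words)
    psi = np.log(np.full(n_words, doc_length / n_words))
    alpha = rng.normal(0.0, 0.3, size=n_docs)
    mu = np.exp(alpha[:, None] + psi[None, :] + np.outer(theta, beta))
    Y = rng.poisson(mu)
    # regenerate degenerate rows/columns rather than silently dropping them
    for _ in range(100):
        zr = Y.sum(axis=1) == 0
        zc = Y.sum(axis=0) == 0
        if not zr.any() and not zc.any():
            break
        if zr.any():
            Y[zr] = rng.poisson(mu[zr])
        if zc.any():
            Y[:, zc] = rng.poisson(mu[:, zc])
    doc_ids = [f"doc{i:04d}" for i in range(n_docs)]
    vocab = [f"w{j:04d}" for j in range(n_words)]
    meta = pd.DataFrame({"doc_id": doc_ids, "participant_id": doc_ids,
                         "arm": None, "timepoint": None, "n_attributions": 1})
    dtm = DocumentTermMatrix(
        doc_ids=doc_ids, vocab=vocab, counts=sp.csr_matrix(Y), meta=meta
    )
    return dtm, theta, beta
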