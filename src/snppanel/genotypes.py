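"""Diploid genotype calling from per-site allele counts.

A three-genotype binomial likelihood model with a single per-read miscall
rate eps: given ``n = ref_count + alt_count`` informative reads of which
``k`` show the alternate allele,

    P(k | hom-ref) = Binom(k; n, eps)
    P(k | het)     = Binom(k; n, 1/2)
    P(k | hom-alt) = Binom(k; n, 1 - eps)

Posteriors combine these with a genotype prior (flat by default) and the MAP
genotype is reported.  The phred-like site quality is

    Q = -10 * log10 P(hom-ref | data)

i.e. confidence that the site is variant in this sample, so hom-ref sites
score near 0 and well-supported variant sites score in the hundreds.  Q is
uncapped; a floating-point floor on the posterior keeps it finite.

Reads showing neither the reference nor the alternate allele (``other_count``)
are treated as noise and excluded from the binomial trials.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom

from .io import CALL_COLUMNS

GENOTYPES = ("hom-ref", "het", "hom-alt")
NO_CALL = "no-call"

FLAT_PRIOR = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)

# Floor on log-posterior terms: prevents -inf Q / log10(0) at extreme counts.
_LOG_FLOOR = np.log(np.finfo(float).tiny)  # ~ -708

_LOG10 = np.log(10.0)


@dataclasses.dataclass
class SiteObservation:
    """Allele-count evidence at one position of one parent."""

    scaffold: str
    position: int  # 1-based
    ref_base: str
    depth: int
    ref_count: int
    alt_count: int
    other_count: int = 0
    alt_base: str | None = None
    gap_count: int = 0

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        if self.ref_count + self.alt_count + self.other_count != self.depth:
            raise ValueError("ref_count + alt_count + other_count must equal depth")


@dataclasses.dataclass
class GenotypeCall:
    """MAP diploid genotype with likelihoods, posterior and variant quality."""

    genotype: str
    log_likelihoods: tuple[float, float, float]
    posterior: tuple[float, float, float]
    quality_Q: float


def _validate_model(error_rate: float, prior) -> np.ndarray:
    if not 0.0 < error_rate < 0.5:
        raise ValueError(f"error_rate must lie in (0, 0.5), got {error_rate}")
    prior = np.asarray(prior, dtype=float)
    if prior.shape != (3,) or np.any(prior < 0) or abs(prior.sum() - 1.0) > 1e-9:
        raise ValueError("prior must be three non-negative weights summing to 1")
    return prior


def genotype_log_likelihoods(
    ref_count, alt_count, error_rate: float
) -> np.ndarray:
    """Log-likelihood of each genotype; vectorised, shape (..., 3).

    Trials are ``ref_count + alt_count``; ``other_count`` reads carry no
    information about the two modelled alleles.
    """
    ref_count = np.asarray(ref_count)
    alt_count = np.asarray(alt_count)
    n = ref_count + alt_count
    probs = np.array([error_rate, 0.5, 1.0 - error_rate])
    return binom.logpmf(alt_count[..., None], n[..., None], probs)


def call_genotype(
    obs: SiteObservation,
    error_rate: float = 0.01,
    prior=FLAT_PRIOR,
) -> GenotypeCall:
    """Call the MAP genotype at one site.

    Zero depth yields a no-call with Q = 0 rather than an error: absence of
    reads is an expected state of a pileup, not a malformed input.
    """
    prior_arr = _validate_model(error_rate, prior)
    if obs.depth == 0:
        flat = (1.0 / 3.0,) * 3
        return GenotypeCall(NO_CALL, (0.0, 0.0, 0.0), flat, 0.0)

    loglik = genotype_log_likelihoods(obs.ref_count, obs.alt_count, error_rate)
    with np.errstate(divide="ignore"):
        log_unnorm = loglik + np.log(prior_arr)
    log_post = log_unnorm - logsumexp(log_unnorm)
    log_post = np.maximum(log_post, _LOG_FLOOR)
    posterior = np.exp(log_post)
    posterior /= posterior.sum()

    genotype = GENOTYPES[int(np.argmax(log_post))]
    quality = max(0.0, -10.0 * log_post[0] / _LOG10)
    return GenotypeCall(
        genotype=genotype,
        log_likelihoods=tuple(float(x) for x in loglik),
        posterior=tuple(float(x) for x in posterior),
        quality_Q=float(quality),
    )


def site_quality(call: GenotypeCall) -> float:
    """Phred-like variant quality: -10 log10 of the hom-ref posterior."""
    p_homref = max(call.posterior[0], np.finfo(float).tiny)
    return max(0.0, -10.0 * np.log10(p_homref))


def call_table(
    pileup: pd.DataFrame,
    error_rate: float = 0.01,
    prior=FLAT_PRIOR,
) -> pd.DataFrame:
    """Vectorised genotype calling over a whole pileup table.

    Returns the standard call table (scaffold, pos, ref, alt, genotype, Q,
    depth, gap_count).  Rows with zero informative reads but positive depth
    keep the prior and hence call the prior's argmax (hom-ref for a flat
    prior, by first-index tie-break).
    """
    prior_arr = _validate_model(error_rate, prior)
    ref_count = pileup["ref_count"].to_numpy()
    alt_count = pileup["alt_count"].to_numpy()
    depth = pileup["depth"].to_numpy()

    loglik = genotype_log_likelihoods(ref_count, alt_count, error_rate)
    with np.errstate(divide="ignore"):
        log_unnorm = loglik + np.log(prior_arr)
    log_post = log_unnorm - logsumexp(log_unnorm, axis=-1, keepdims=True)
    log_post = np.maximum(log_post, _LOG_FLOOR)

    genotype = np.array(GENOTYPES, dtype=object)[np.argmax(log_post, axis=-1)]
    quality = np.maximum(0.0, -10.0 * log_post[..., 0] / _LOG10)
    no_data = depth == 0
    genotype[no_data] = NO_CALL
    quality[no_data] = 0.0

    return pd.DataFrame(
        {
            "scaffold": pileup["scaffold"].to_numpy(),
            "pos": pileup["pos"].to_numpy(),
            "ref": pileup["ref_base"].to_numpy(),
            "alt": pileup["alt_base"].to_numpy(),
            "genotype": genotype,
            "Q": quality,
            "depth": depth,
            "gap_count": pileup["gap_count"].to_numpy(),
        }
    )[CALL_COLUMNS]
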