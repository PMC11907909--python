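"""Library-size and trimmed-mean-of-M-values (TMM) normalization.

TMM corrects between-sample composition bias in count data: a handful of
strongly selected guides can consume a large share of a sample's reads and
make every unselected guide look depleted.  The scale factor for a sample
is derived from the precision-weighted mean of per-guide log-ratios (M
values) against a reference sample, after doubly trimming extreme M and A
(average log-abundance) values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .io import CountMatrix, ScreenFormatError

__all__ = ["NormFactors", "tmm_factors", "normalized_log_abundance"]


@dataclass(frozen=True)
class NormFactors:
    """Per-sample library sizes and TMM scale factors (geometric mean 1)."""

    sample_ids: tuple[str, ...]
    library_size: np.ndarray
    tmm_factor: np.ndarray
    reference: str

    def __post_init__(self):
        if (np.asarray(self.tmm_factor) <= 0).any():
            raise ScreenFormatError(["TMM factors must be positive"])
        object.__setattr__(self, "library_size", np.asarray(self.library_size, dtype=float))
        object.__setattr__(self, "tmm_factor", np.asarray(self.tmm_factor, dtype=float))

    @property
    def effective_size(self) -> np.ndarray:
        """library_size x tmm_factor, the scale used in model offsets."""
        return self.library_size * self.tmm_factor


def _pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """log2 TMM factor of one sample against the reference.

    Guides with a zero in either member are excluded; trimming is
    rank-based (ties averaged) at the given fractions on both the M and A
    axes; the retained M values are averaged with inverse delta-method
    variance weights.
    """
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        raise ScreenFormatError(["sample shares no positive guide with the reference"])
    p_obs = obs[keep] / n_obs
    p_ref = ref[keep] / n_ref
    m = np.log2(p_obs / p_ref)
    a = (np.log2(p_obs) + np.log2(p_ref)) / 2.0
    # delta-method variance of M for binomial counts
    v = (n_obs - obs[keep]) / (n_obs * obs[keep]) + (n_ref - ref[keep]) / (n_ref * ref[keep])
    if np.max(np.abs(m)) < 1e-6:
        return 0.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not sel.any():
        return 0.0
    f = np.sum(m[sel] / v[sel]) / np.sum(1.0 / v[sel])
    return float(f) if np.isfinite(f) else 0.0


def _pick_reference(counts: np.ndarray, lib_size: np.ndarray, sample_ids) -> int:
    """Reference = sample whose upper-quartile normalized abundance is
    closest to the across-sample mean; lexicographic tie-break on id."""
    f75 = np.quantile(counts / lib_size, 0.75, axis=0)
    dist = np.abs(f75 - f75.mean())
    best = np.min(dist)
    candidates = [i for i in range(len(sample_ids)) if dist[i] == best]
    return min(candidates, key=lambda i: sample_ids[i])


def tmm_factors(
    counts: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    reference: str | None = None,
) -> NormFactors:
    """Compute TMM scale factors for every sample of a count matrix.

    Parameters
    ----------
    counts
        Guide x sample integer counts; >= 2 samples, each with a positive
        total.
    trim_m, trim_a
        Two-sided trim fractions applied to the M (log-ratio) and A
        (average log-abundance) axes.  Defaults are the published TMM
        defaults (0.30 and 0.05).
    reference
        Sample id to use as the TMM reference; by default chosen by the
        upper-quartile rule.

    Returns
    -------
    NormFactors with factors rescaled to geometric mean 1.
    """
    y = counts.counts.astype(float)
    if counts.n_samples < 2:
        raise ScreenFormatError(["TMM needs at least 2 samples"])
    lib = y.sum(axis=0)
    zero_tot = [counts.sample_ids[j] for j in np.flatnonzero(lib <= 0)]
    if zero_tot:
        raise ScreenFormatError([f"sample {s!r} has zero total count" for s in zero_tot])
    if reference is None:
        ref_idx = _pick_reference(y, lib, counts.sample_ids)
    else:
        if reference not in counts.sample_ids:
            raise ScreenFormatError([f"reference sample {reference!r} not in counts"])
        ref_idx = counts.sample_ids.index(reference)
    log_f = np.zeros(counts.n_samples)
    for j in range(counts.n_samples):
        if j == ref_idx:
            continue
        log_f[j] = _pair_factor(y[:, j], y[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a)
    factors = 2.0 ** (log_f - log_f.mean())  # rescale to geometric mean 1
    return NormFactors(counts.sample_ids, lib, factors, counts.sample_ids[ref_idx])


def normalized_log_abundance(
    counts: CountMatrix, factors: NormFactors, prior: float = 0.5
) -> np.ndarray:
    """log2 abundance per million on the TMM-normalized scale.

    value = log2((count + prior) / (library_size * tmm_factor + 2*prior) * 1e6)
    """
    if tuple(factors.sample_ids) != tuple(counts.sample_ids):
        raise ScreenFormatError(["norm factors computed on different samples"])
    eff = factors.effective_size + 2.0 * prior
    return np.log2((counts.counts + prior) / eff * 1e6)
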