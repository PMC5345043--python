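"""Deterministic preprocessing of raw items into analysis-ready responses.

Implements the recoding and filtering rules used before factor screening
and IRT calibration:

* direction recoding so that higher values always indicate worse health;
* three-level banding of continuous measured tests (percentile bands for
  the walking-speed time, mean +/- 1 SD bands for cognitive tests);
* binary recode of the orientation-in-time test;
* missingness filters (baseline participants with >= 25% of items missing
  are excluded from the factor analysis; person-waves with more than half
  of the administered items missing are excluded from the IRT);
* anchor / wave-varying item classification and the stratified
  development/validation split.

All operations are pure and idempotent where re-application makes sense.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from healthtrait.panel import MISSING, UNAVAILABLE, ItemCatalog, ResponsePanel

logger = logging.getLogger(__name__)

__all__ = [
    "recode_direction",
    "band_percentile",
    "band_sd",
    "recode_orientation",
    "filter_participants_fa",
    "filter_personwave_irt",
    "classify_items",
    "split_sample",
]


def recode_direction(values, current_direction: str, n_categories: int | None = None):
    """Reverse an ordinal item so that higher values indicate worse health.

    ``higher_is_worse`` input is returned unchanged; ``higher_is_better``
    is mapped ``x -> (K - 1) - x``.  Applying the function twice (with the
    flipped direction flag) returns the input.  NaN propagates.
    """
    values = np.asarray(values, dtype=float)
    if current_direction == "higher_is_worse":
        return values.copy()
    if current_direction != "higher_is_better":
        raise ValueError(f"unknown direction flag {current_direction!r}")
    if n_categories is None:
        if np.all(np.isnan(values)):
            raise ValueError("cannot infer category count from all-missing input")
        n_categories = int(np.nanmax(values)) + 1
    return (n_categories - 1) - values


def band_percentile(values) -> np.ndarray:
    """Three-level banding by the empirical 25th/75th percentiles.

    Intended for the walking-speed *time*: times below the 25th percentile
    are the fast (healthiest) group 0, times above the 75th percentile the
    slow group 2, the interquartile range is the middle group 1.  Boundary
    values fall into the middle band; percentiles use linear interpolation;
    missing propagates.
    """
    values = np.asarray(values, dtype=float)
    obs = values[~np.isnan(values)]
    if obs.size == 0:
        raise ValueError("all values missing; cannot band")
    if obs.size < 4:
        raise ValueError("need >= 4 non-missing values to estimate quartiles")
    q25, q75 = np.percentile(obs, [25, 75])
    out = np.full(values.shape, np.nan)
    m = ~np.isnan(values)
    out[m] = 1.0
    out[m & (values < q25)] = 0.0
    out[m & (values > q75)] = 2.0
    return out


def band_sd(values) -> np.ndarray:
    """Three-level banding by mean +/- 1 SD of the non-missing values.

    Intended for test scores where higher raw performance is better:
    scores above mean+SD become group 0 (best), scores below mean-SD
    group 2, everything within one SD (boundaries included) group 1.
    Banding is affine-invariant; missing propagates.
    """
    values = np.asarray(values, dtype=float)
    obs = values[~np.isnan(values)]
    if obs.size == 0:
        raise ValueError("all values missing; cannot band")
    mean, sd = obs.mean(), obs.std(ddof=1) if obs.size > 1 else 0.0
    if sd == 0:
        raise ValueError("zero standard deviation; banding undefined")
    out = np.full(values.shape, np.nan)
    m = ~np.isnan(values)
    out[m] = 1.0
    out[m & (values > mean + sd)] = 0.0
    out[m & (values < mean - sd)] = 2.0
    return out


def recode_orientation(correct_count):
    """Binary recode of the 4-question orientation test.

    All four correct -> 0 ("no difficulty"); any failure -> 1 ("some
    difficulties").  Accepts scalars or arrays of counts in {0..4}.
    """
    arr = np.asarray(correct_count, dtype=float)
    valid = np.isnan(arr) | ((arr >= 0) & (arr <= 4))
    if not valid.all():
        raise ValueError("orientation counts must lie in 0..4")
    out = np.where(np.isnan(arr), np.nan, (arr < 4).astype(float))
    return float(out) if np.isscalar(correct_count) else out


def filter_participants_fa(
    panel: ResponsePanel, threshold: float = 0.25
) -> tuple[ResponsePanel, dict]:
    """Drop persons missing at least ``threshold`` of the baseline items.

    The missing fraction is taken over items administered at baseline.
    The rule is non-strict (fraction >= threshold excludes), so a person
    missing exactly a quarter of the items is removed.
    """
    base = panel.wave(1)
    administered = base != UNAVAILABLE
    n_admin = administered.sum(axis=1)
    if np.all(n_admin == 0):
        raise ValueError("no administered items at baseline")
    frac = np.divide(
        (base == MISSING).sum(axis=1), n_admin, out=np.ones(panel.n_persons), where=n_admin > 0
    )
    keep = frac < threshold
    report = {
        "n_total": panel.n_persons,
        "n_retained": int(keep.sum()),
        "n_excluded": int((~keep).sum()),
        "threshold": threshold,
        "excluded_person_ids": list(np.asarray(panel.person_ids)[~keep]),
    }
    filtered = ResponsePanel(panel.data[keep], np.asarray(panel.person_ids)[keep], panel.item_names)
    return filtered, report


def filter_personwave_irt(
    panel: ResponsePanel, threshold: float = 0.5
) -> tuple[ResponsePanel, np.ndarray]:
    """Exclude person-waves with more than half of administered items missing.

    The rule is strict: exactly half missing is retained.  Excluded rows
    have their cells set to structurally unavailable; a boolean inclusion
    mask (n_persons, n_waves) is returned alongside.  Idempotent.
    """
    administered = panel.data != UNAVAILABLE
    n_admin = administered.sum(axis=2)
    n_miss = (panel.data == MISSING).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_admin > 0, n_miss / np.maximum(n_admin, 1), 1.0)
    include = (n_admin > 0) & (frac <= threshold)
    if np.any(n_admin == 0):
        warnings.warn("person-waves with no administered items were dropped")
    out = panel.copy()
    out.data[~include, :] = UNAVAILABLE
    return out, include


def classify_items(catalog: ItemCatalog) -> tuple[list[str], list[str]]:
    """Split the catalog into anchor items (fielded in every wave) and
    wave-varying items (absent somewhere)."""
    anchors = [it.name for it in catalog if it.is_anchor]
    varying = [it.name for it in catalog if not it.is_anchor]
    return anchors, varying


def split_sample(
    person_ids,
    frac: float = 0.7,
    stratify=None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded development/validation split, optionally stratified.

    Returns disjoint, exhaustive arrays of person ids with the development
    share within one person of ``frac`` inside every stratum.
    """
    if not (0 < frac < 1):
        raise ValueError("frac must lie in (0, 1)")
    person_ids = np.asarray(person_ids)
    rng = np.random.default_rng(seed)
    strata = np.zeros(person_ids.size, dtype=int) if stratify is None else np.asarray(stratify)
    dev_parts, val_parts = [], []
    for s in np.unique(strata):
        ids = person_ids[strata == s]
        perm = rng.permutation(ids.size)
        n_dev = int(round(frac * ids.size))
        dev_parts.append(ids[perm[:n_dev]])
        val_parts.append(ids[perm[n_dev:]])
    return np.sort(np.concatenate(dev_parts)), np.sort(np.concatenate(val_parts))
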