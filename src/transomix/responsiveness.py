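"""Glucose-responsiveness calling per genotype.

A molecule is called glucose-responsive in a genotype when, at any
post-bolus time point, its q-value is at or below ``q_threshold`` and the
absolute log2 fold change versus the 0-min fasting baseline is at or above
``fc_threshold_log2``.  The direction of the call is the sign of the fold
change at the earliest significant time point; the response speed comes from
the half-response time T1/2 (rapid < 20 min, slow > 60 min).
"""

from __future__ import annotations

import logging
import math
from typing import Callable

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .datatypes import OmicsTimeCourse
from .stats import storey_qvalues, welch_test

logger = logging.getLogger(__name__)

DIRECTIONS = ("increase", "decrease", "none")
SPEEDS = ("rapid", "intermediate", "slow", "undefined")
RESPONSE_CLASSES = ("WT_specific", "OB_specific", "common", "opposite", "none")


# ---------------------------------------------------------------------------
# Detection filter and fold changes
# ---------------------------------------------------------------------------


def filter_detected(tc: OmicsTimeCourse, min_fraction: float = 0.5) -> OmicsTimeCourse:
    """Drop molecules under-detected at any post-bolus point in either genotype.

    A molecule is removed when, for some genotype and some time point after
    administration, the fraction of non-missing replicates is strictly below
    ``min_fraction`` (the published rule reads "less than half", so exactly
    half survives).
    """
    keep = pd.Series(True, index=tc.data.index)
    for g in tc.genotypes:
        for t in tc.time_points:
            if t == 0:
                continue
            block = tc.block(g, t)
            frac = block.notna().mean(axis=1)
            keep &= frac >= min_fraction
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_detected[%s]: removed %d of %d molecules", tc.layer, removed, len(keep))
    return OmicsTimeCourse(tc.layer, tc.data.loc[keep])


def log2_fold_changes(tc: OmicsTimeCourse) -> pd.DataFrame:
    """log2( mean(t) / mean(0) ) per molecule for every genotype and t > 0.

    Means are arithmetic over non-missing replicates on the raw scale.
    Molecules with a zero or missing baseline mean get NaN fold changes for
    that genotype (flagged; excluded from responsiveness calls).
    """
    blocks = {}
    for g in tc.genotypes:
        means = tc.mean_traces(g)
        base = means[0]
        ok = base > 0
        fc = np.log2(means.loc[:, means.columns != 0].div(base.where(ok), axis=0))
        n_bad = int((~ok).sum())
        if n_bad:
            logger.warning(
                "log2_fold_changes[%s/%s]: %d molecules with zero/missing baseline",
                tc.layer, g, n_bad,
            )
        blocks[g] = fc
    out = pd.concat(blocks, axis=1)
    out.columns = out.columns.set_names(["genotype", "time"])
    return out


# ---------------------------------------------------------------------------
# Per-time-point tests
# ---------------------------------------------------------------------------

_COUNT_TESTS: dict[str, Callable] = {}


def register_count_test(name: str, fn: Callable) -> None:
    """Register a two-group count test ``fn(a, b) -> p`` under ``name``."""
    _COUNT_TESTS[name] = fn


def _welch_log2_count_test(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.nansum(a) == 0 and np.nansum(b) == 0:
        return 1.0
    return welch_test(np.log2(a + 1.0), np.log2(b + 1.0)).p


register_count_test("welch_log2", _welch_log2_count_test)


def scale_to_median_library(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample (column) to the per-layer median total count."""
    totals = counts.sum(axis=0, skipna=True)
    median = float(totals.median())
    safe = totals.replace(0, np.nan)
    return counts.div(safe, axis=1) * median


def count_test(a, b, *, method: str = "welch_log2",
               lib_a=None, lib_b=None, median_total: float | None = None) -> float:
    """Pluggable two-group test for count replicates.

    The default scales counts by library size to a common ``median_total``
    and applies Welch's t on log2(count + 1); with equal library sizes the
    scaling is the identity.  Alternative methods registered through
    :func:`register_count_test` are dispatched by name.
    """
    if method not in _COUNT_TESTS:
        raise KeyError(f"unknown count test {method!r}; registered: {sorted(_COUNT_TESTS)}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if lib_a is not None or lib_b is not None:
        lib_a = np.asarray(lib_a, dtype=float)
        lib_b = np.asarray(lib_b, dtype=float)
        if median_total is None:
            median_total = float(np.median(np.concatenate([lib_a, lib_b])))
        a = a / lib_a * median_total
        b = b / lib_b * median_total
    return _COUNT_TESTS[method](a, b)


def timepoint_pvalues(tc: OmicsTimeCourse, *, method: str | None = None) -> pd.DataFrame:
    """Per-molecule p-values for each genotype and post-bolus time vs 0 min.

    Metabolite and phospho layers use the two-tailed Welch test on raw
    replicate abundances; the gene layer uses the registered count test on
    library-size-scaled counts.
    """
    is_counts = tc.layer == "gene"
    data = tc.data
    if is_counts:
        scaled = scale_to_median_library(tc.data)
        data = scaled
        test = _COUNT_TESTS[method or "welch_log2"]
    cols = {}
    for g in tc.genotypes:
        base = data.xs((g, 0), axis=1, level=(0, 1)).to_numpy(dtype=float)
        for t in tc.time_points:
            if t == 0:
                continue
            now = data.xs((g, t), axis=1, level=(0, 1)).to_numpy(dtype=float)
            if is_counts:
                p = np.array([test(base[i], now[i]) for i in range(base.shape[0])])
            else:
                p = np.array([welch_test(base[i], now[i]).p for i in range(base.shape[0])])
            cols[(g, t)] = p
    out = pd.DataFrame(cols, index=tc.data.index)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["genotype", "time"])
    return out


def baseline_difference_qvalues(tc: OmicsTimeCourse, *, method: str = "welch_log2") -> pd.Series:
    """Storey q-values for the 0-min WT-vs-OB contrast, per molecule.

    Used by the clustering selection filter: genes already different between
    genotypes in the fasting state enter the clustering even without a
    post-bolus response.
    """
    data = scale_to_median_library(tc.data) if tc.layer == "gene" else tc.data
    wt0 = data.xs(("WT", 0), axis=1, level=(0, 1)).to_numpy(dtype=float)
    ob0 = data.xs(("OB", 0), axis=1, level=(0, 1)).to_numpy(dtype=float)
    if tc.layer == "gene":
        test = _COUNT_TESTS[method]
        p = np.array([test(wt0[i], ob0[i]) for i in range(wt0.shape[0])])
    else:
        p = np.array([welch_test(wt0[i], ob0[i]).p for i in range(wt0.shape[0])])
    q = np.full(p.size, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        q[ok] = storey_qvalues(p[ok])
    return pd.Series(q, index=tc.data.index, name="baseline_q")


def qvalues_from_pvalues(p: pd.DataFrame, *, pooling: str = "per_time") -> pd.DataFrame:
    """Storey q-values across molecules.

    ``per_time`` pools p-values across molecules separately for every
    (genotype, time) column; ``pooled`` pools one vector per genotype across
    all times.  NaN p-values (undefined tests) stay NaN and do not enter the
    pool.
    """
    q = pd.DataFrame(np.nan, index=p.index, columns=p.columns)
    if pooling == "per_time":
        for col in p.columns:
            vec = p[col]
            ok = vec.notna()
            if ok.sum() > 0:
                q.loc[ok, col] = storey_qvalues(vec[ok].to_numpy())
    elif pooling == "pooled":
        for g in p.columns.get_level_values(0).unique():
            sub = p[g]
            flat = sub.to_numpy().ravel()
            ok = ~np.isnan(flat)
            if ok.sum() > 0:
                qflat = np.full(flat.size, np.nan)
                qflat[ok] = storey_qvalues(flat[ok])
                q[g] = qflat.reshape(sub.shape)
    else:
        raise ValueError("pooling must be 'per_time' or 'pooled'")
    return q


# ---------------------------------------------------------------------------
# Half-response time
# ---------------------------------------------------------------------------


def half_time(times, trace, direction: str) -> float | None:
    """First time the trace crosses half of its extremal deviation.

    ``trace`` is a mean time course sampled at ``times`` (minutes, starting
    at the baseline).  The amplitude is the extremum of ``trace - trace[0]``
    in the called direction across all time points; T1/2 is the first
    crossing of baseline + amplitude/2, linearly interpolated between
    samples.  Returns None for a flat trace (undefined).
    """
    times = np.asarray(times, dtype=float)
    trace = np.asarray(trace, dtype=float)
    if direction not in ("increase", "decrease"):
        raise ValueError("direction must be 'increase' or 'decrease'")
    dev = trace - trace[0]
    amp = dev.max() if direction == "increase" else dev.min()
    if amp == 0 or not np.isfinite(amp):
        return None
    half = trace[0] + amp / 2.0
    for i in range(1, len(times)):
        prev, cur = trace[i - 1], trace[i]
        crossed = (prev < half <= cur) if amp > 0 else (prev > half >= cur)
        if crossed:
            return float(times[i - 1] + (half - prev) / (cur - prev) * (times[i] - times[i - 1]))
    return None


def speed_class(t_half: float | None, config: PipelineConfig) -> str:
    """rapid below 20 min, slow above 60 min, intermediate in between."""
    if t_half is None or (isinstance(t_half, float) and math.isnan(t_half)):
        return "undefined"
    if t_half < config.rapid_max_min:
        return "rapid"
    if t_half > config.slow_min_min:
        return "slow"
    return "intermediate"


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------


def call_responsiveness(
    log2fc: pd.DataFrame,
    q: pd.DataFrame,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Apply the q-and-fold conjunction at every time point per genotype.

    Returns a table indexed by molecule with one row per (molecule, genotype)
    and columns responsive, direction, earliest_sig_time.
    """
    rows = []
    genotypes = list(log2fc.columns.get_level_values(0).unique())
    for g in genotypes:
        fc_g = log2fc[g]
        q_g = q[g]
        times = sorted(fc_g.columns)
        sig = (q_g[times] <= config.q_threshold) & (
            fc_g[times].abs() >= config.fc_threshold_log2
        )
        for mol in fc_g.index:
            hit_times = [t for t in times if bool(sig.loc[mol, t])]
            if hit_times:
                t0 = hit_times[0]
                d = "increase" if fc_g.loc[mol, t0] > 0 else "decrease"
                rows.append((mol, g, True, d, t0))
            else:
                rows.append((mol, g, False, "none", np.nan))
    out = pd.DataFrame(
        rows, columns=["molecule_id", "genotype", "responsive", "direction", "earliest_sig_time"]
    )
    return out.set_index(["molecule_id", "genotype"])


def attach_half_times(
    calls: pd.DataFrame,
    log2fc: pd.DataFrame,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Add t_half and speed per responsive molecule/genotype.

    T1/2 is measured on the log2 fold-change trace (baseline 0 at t = 0),
    the same scale on which responsiveness and amplitude are defined.
    """
    t_half = pd.Series(np.nan, index=calls.index, dtype=float)
    speed = pd.Series("undefined", index=calls.index, dtype=object)
    for (mol, g), row in calls.iterrows():
        if not row["responsive"]:
            continue
        times = [0] + sorted(log2fc[g].columns)
        trace = np.concatenate([[0.0], log2fc[g].loc[mol, sorted(log2fc[g].columns)].to_numpy()])
        th = half_time(times, trace, row["direction"])
        if th is None:
            logger.warning("flat trace for responsive molecule %s/%s: T1/2 undefined", mol, g)
            continue
        t_half.loc[(mol, g)] = th
        speed.loc[(mol, g)] = speed_class(th, config)
    out = calls.copy()
    out["t_half"] = t_half
    out["speed"] = speed
    return out


def response_class(wt_responsive: bool, wt_direction: str,
                   ob_responsive: bool, ob_direction: str) -> str:
    """Cross-genotype class of one molecule."""
    if wt_responsive and ob_responsive:
        return "common" if wt_direction == ob_direction else "opposite"
    if wt_responsive:
        return "WT_specific"
    if ob_responsive:
        return "OB_specific"
    return "none"


def response_classes(calls: pd.DataFrame) -> pd.Series:
    """Class per molecule from the per-genotype call table."""
    out = {}
    molecules = calls.index.get_level_values(0).unique()
    for mol in molecules:
        def _get(g):
            if (mol, g) in calls.index:
                row = calls.loc[(mol, g)]
                return bool(row["responsive"]), row["direction"]
            return False, "none"
        wr, wd = _get("WT")
        obr, obd = _get("OB")
        out[mol] = response_class(wr, wd, obr, obd)
    return pd.Series(out, name="response_class")


def respond(tc: OmicsTimeCourse, config: PipelineConfig) -> pd.DataFrame:
    """Full responsiveness analysis for one layer.

    Runs the detection filter, fold changes, per-time tests, Storey q-values,
    the calling conjunction, and T1/2 assignment.  Returns the per-(molecule,
    genotype) call table with per-time log2fc/p/q attached as extra columns
    (``log2fc_<t>``, ``p_<t>``, ``q_<t>``).
    """
    tc = filter_detected(tc, config.min_detected_fraction)
    fc = log2_fold_changes(tc)
    p = timepoint_pvalues(tc, method=config.count_test_method)
    q = qvalues_from_pvalues(p, pooling=config.qvalue_pooling)
    # undefined fold changes (zero baseline) or undefined tests can never
    # satisfy the conjunction: mask them to the non-significant extremes
    fc_for_calls = fc.fillna(0.0)
    calls = call_responsiveness(fc_for_calls, q.fillna(1.0), config)
    calls = attach_half_times(calls, fc_for_calls, config)
    n_resp = calls.groupby(level="genotype")["responsive"].sum()
    logger.info("respond[%s]: molecules in=%d, responsive per genotype=%s",
                tc.layer, tc.data.shape[0], n_resp.to_dict())
    extras = []
    for name, table in (("log2fc", fc), ("p", p), ("q", q)):
        wide = table.stack(level="genotype", future_stack=True)
        wide.index = wide.index.set_names(["molecule_id", "genotype"])
        wide.columns = [f"{name}_{t}" for t in wide.columns]
        extras.append(wide)
    return calls.join(pd.concat(extras, axis=1))
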