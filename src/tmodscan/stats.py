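"""Modification-site calling from misincorporation counts.

At a genuinely modified position the reverse transcriptase leaves a
signature spread over several event types: elevated rates of more than one
base substitution and of deletions.  The caller exploits this: for every
site and sample, each substitution away from the reference base (and, by
default, the deletion event) is tested against the sample-wide background
rate of that event type with an exact one-sided binomial test.  The
resulting per-event p-values are winsorized — the single smallest and
single largest are removed, so a lone outlier event can neither carry nor
sink a site — and merged with Fisher's method into one p-value per site.
Within each sample, Benjamini-Hochberg correction is applied across all
coverage-eligible sites, and a site is reported as modified if it reaches
``FDR < fdr`` at ``coverage >= min_cov`` in at least one sample.

Background rates are pooled count ratios per ordered substitution type
(e.g. G->A), estimated after a one-pass trimming of candidate modified
positions; this keeps strong modification signals from inflating the
background they are tested against.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .pileup import BASES

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300
PI_FLOOR = 1e-6
OUTLIER_FOLD = 10.0

SITECALL_COLUMNS = [
    "target_id", "pos", "ref", "coverage", "combined_p", "q_value", "passes",
]


@dataclass
class BackgroundModel:
    """Per-sample background rate of each misincorporation event type.

    ``rates`` maps (ref_base, alt) -> rate, where alt is one of the three
    other bases or ``"del"``.  Substitution rates are alt counts over
    base-call coverage at positions with that reference base; deletion rates
    use coverage + deletions as the denominator.  Event types with no
    informative positions are absent (tests against them return p = 1).
    """

    rates: dict[tuple[str, str], float]
    n_positions_used: int = 0
    n_positions_trimmed: int = 0

    def rate(self, ref: str, alt: str) -> float | None:
        return self.rates.get((ref, alt))


def estimate_background(frame: pd.DataFrame) -> BackgroundModel:
    """Estimate background event rates from one sample's pileup table.

    Positions whose total mismatch rate exceeds ``OUTLIER_FOLD`` times the
    median positive mismatch rate are excluded (one pass) as candidate
    modified sites; rates are floored at ``PI_FLOOR``.
    """
    covered = frame[frame["coverage"] > 0]
    if covered.empty:
        raise ValueError("cannot estimate background: no covered position")
    rate = covered["error_rate"].to_numpy(float)
    positive = rate[rate > 0]
    if positive.size:
        cutoff = OUTLIER_FOLD * float(np.median(positive))
        keep = covered[rate <= cutoff]
    else:
        keep = covered
    n_trimmed = len(covered) - len(keep)
    if n_trimmed:
        logger.info("background estimation trimmed %d outlier positions", n_trimmed)
    rates: dict[tuple[str, str], float] = {}
    for ref, grp in keep.groupby("ref"):
        if ref not in BASES:
            continue
        cov = float(grp["coverage"].sum())
        dels = float(grp["del"].sum())
        if cov > 0:
            for alt in BASES:
                if alt != ref:
                    rates[(ref, alt)] = max(float(grp[alt].sum()) / cov, PI_FLOOR)
        if cov + dels > 0:
            rates[(ref, "del")] = max(dels / (cov + dels), PI_FLOOR)
    return BackgroundModel(
        rates=rates, n_positions_used=len(keep), n_positions_trimmed=n_trimmed
    )


def test_event(k: int, n: int, pi: float) -> float:
    """Exact one-sided binomial tail P(X >= k | n, pi)."""
    if n == 0 or k <= 0:
        return 1.0
    if not 0.0 < pi < 1.0:
        raise ValueError(f"background rate must be in (0,1), got {pi}")
    if not 0 <= k <= n:
        raise ValueError(f"invalid counts k={k}, n={n}")
    return float(sps.binom.sf(k - 1, n, pi))


def winsorize_pvalues(p_list: Sequence[float]) -> list[float]:
    """Drop exactly one minimal and one maximal p-value (ties: one occurrence
    each); lists shorter than 3 are returned unchanged."""
    p = list(p_list)
    if not p:
        raise ValueError("empty p-value list")
    if len(p) < 3:
        logger.debug("winsorization skipped: only %d p-values", len(p))
        return p
    p.sort()
    return p[1:-1]


def fisher_combine(p_list: Sequence[float]) -> float:
    """Fisher's method: -2 sum(ln p) ~ chi^2 with 2m degrees of freedom."""
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    x2 = -2.0 * np.log(np.maximum(p, P_FLOOR)).sum()
    return float(sps.chi2.sf(x2, 2 * p.size))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ModificationCallSet:
    """Result of calling sites over a set of samples.

    ``sites`` is the union, over samples, of sites passing the coverage and
    FDR gates; ``per_sample`` retains the full audit trail (per-event
    p-values, combined p, q, pass flag per site and sample).
    """

    sites: list[tuple[str, int]]
    per_sample: dict[str, pd.DataFrame]
    params: dict

    def passes_by_sample(self, target_id: str, pos: int) -> dict[str, bool]:
        out = {}
        for sample, frame in self.per_sample.items():
            row = frame[(frame["target_id"] == target_id) & (frame["pos"] == pos)]
            out[sample] = bool(row["passes"].any())
        return out


def _event_pvalues(
    frame: pd.DataFrame, bg: BackgroundModel, events: str
) -> tuple[np.ndarray, list[str]]:
    """Per-event p-value matrix (n_sites, n_events) for one sample."""
    n = len(frame)
    ref = frame["ref"].to_numpy(str)
    cov = frame["coverage"].to_numpy(np.int64)
    labels = ["sub1", "sub2", "sub3"] + (["del"] if events == "subs+del" else [])
    P = np.ones((n, len(labels)))
    warned: set[tuple[str, str]] = set()
    for b in BASES:
        rows = np.nonzero(ref == b)[0]
        if rows.size == 0:
            continue
        alts = [a for a in BASES if a != b]
        for ei, alt in enumerate(alts):
            pi = bg.rate(b, alt)
            if pi is None:
                if (b, alt) not in warned:
                    logger.warning("no background rate for %s->%s; p=1", b, alt)
                    warned.add((b, alt))
                continue
            k = frame[alt].to_numpy(np.int64)[rows]
            P[rows, ei] = sps.binom.sf(k - 1, cov[rows], pi)
        if events == "subs+del":
            pi = bg.rate(b, "del")
            if pi is None:
                if (b, "del") not in warned:
                    logger.warning("no background deletion rate for %s; p=1", b)
                    warned.add((b, "del"))
                continue
            k = frame["del"].to_numpy(np.int64)[rows]
            n_del = cov[rows] + k
            P[rows, -1] = sps.binom.sf(k - 1, n_del, pi)
    P[cov == 0] = 1.0
    np.clip(P, P_FLOOR, 1.0, out=P)
    return P, labels


def call_sites(
    samples: Mapping[str, pd.DataFrame],
    min_cov: int = 10,
    fdr: float = 0.01,
    events: str = "subs+del",
    backgrounds: Mapping[str, BackgroundModel] | None = None,
) -> ModificationCallSet:
    """Call modified sites across samples.

    Per sample: background estimation -> per-event binomial tests ->
    winsorization -> Fisher merge -> BH correction over the family of all
    sites with ``coverage >= min_cov`` in that sample.  The returned call
    set is the union of sites passing in at least one sample.

    ``events`` selects the per-site event set: ``"subs+del"`` (default; the
    three substitutions away from the reference plus the deletion event, so
    winsorization leaves two p-values) or ``"subs"`` (winsorization then
    leaves a single p-value and Fisher's merge is the identity).
    """
    if not samples:
        raise ValueError("at least one sample required")
    if events not in ("subs", "subs+del"):
        raise ValueError(f"unknown event set {events!r}")
    per_sample: dict[str, pd.DataFrame] = {}
    called: set[tuple[str, int]] = set()
    for sample_id in sorted(samples):
        frame = samples[sample_id].reset_index(drop=True)
        bg = (
            backgrounds[sample_id]
            if backgrounds is not None
            else estimate_background(frame)
        )
        P, labels = _event_pvalues(frame, bg, events)
        m = P.shape[1]
        if m >= 3:
            kept = np.sort(P, axis=1)[:, 1 : m - 1]
        else:
            kept = P
        x2 = -2.0 * np.log(kept).sum(axis=1)
        combined = sps.chi2.sf(x2, 2 * kept.shape[1])
        cov = frame["coverage"].to_numpy(np.int64)
        eligible = cov >= min_cov
        q = np.full(len(frame), np.nan)
        if eligible.any():
            q[eligible] = bh_adjust(combined[eligible])
        passes = eligible & (q < fdr)
        out = frame[["target_id", "pos", "ref", "coverage"]].copy()
        for ei, lab in enumerate(labels):
            out[f"p_{lab}"] = P[:, ei]
        out["combined_p"] = combined
        out["q_value"] = q
        out["passes"] = passes
        per_sample[sample_id] = out
        called.update(
            (t, int(p))
            for t, p in out.loc[passes, ["target_id", "pos"]].itertuples(index=False)
        )
    return ModificationCallSet(
        sites=sorted(called),
        per_sample=per_sample,
        params={"min_cov": min_cov, "fdr": fdr, "events": events},
    )


def write_calls_tsv(path, callset: ModificationCallSet) -> None:
    """Merged calls TSV with a parameter header block (positions 1-based)."""
    with open(path, "w") as fh:
        for key, val in callset.params.items():
            fh.write(f"# {key} = {val}\n")
        fh.write("# positions are 1-based on the mature tRNA sequence\n")
        fh.write("target_id\tpos\n")
        for t, p in callset.sites:
            fh.write(f"{t}\t{p}\n")


def read_calls_tsv(path) -> list[tuple[str, int]]:
    sites = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("target_id"):
                continue
            t, p = line.rstrip("\n").split("\t")
            sites.append((t, int(p)))
    return sites
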