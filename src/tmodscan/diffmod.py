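"""Differential modification analysis between conditions.

Given per-sample pileup tables, a sample sheet and a call set, this module
builds a per-site error-rate table with per-condition means, and classifies
each wild-type-called site against every knockout condition:

* ``lost`` — the site passes in no KO sample of that condition and the WT
  mean error rate exceeds the KO mean by at least ``min_fold``;
* ``retained`` — the site still passes in at least one KO sample;
* ``ambiguous`` — anything else (e.g. non-significant in KO but without a
  clear error-rate drop).

A site losing its misincorporation signature in a knockout attributes the
modification to the knocked-out enzyme.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import ModificationCallSet

KO_RATE_FLOOR = 1e-4


@dataclass
class SampleSheet:
    """Sample -> condition assignment."""

    frame: pd.DataFrame  # columns: sample_id, condition

    def __post_init__(self) -> None:
        missing = {"sample_id", "condition"} - set(self.frame.columns)
        if missing:
            raise ValueError(f"sample sheet misses columns {sorted(missing)}")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "SampleSheet":
        return cls(
            pd.DataFrame(
                {"sample_id": list(mapping), "condition": list(mapping.values())}
            )
        )

    def samples_of(self, condition: str) -> list[str]:
        sel = self.frame[self.frame["condition"] == condition]
        return sorted(sel["sample_id"])

    @property
    def conditions(self) -> list[str]:
        return sorted(self.frame["condition"].unique())


def condition_means(
    sample_pileups: Mapping[str, pd.DataFrame],
    sheet: SampleSheet,
    sites: Sequence[tuple[str, int]],
) -> pd.DataFrame:
    """Per-site per-condition arithmetic mean error rates.

    Samples without base-call coverage at a site are excluded from that
    site's mean, with the number of contributing samples recorded in the
    ``n_<condition>`` column.  Per-sample rates are retained in
    ``rate_<sample>`` columns.  Rows are ordered by (target_id, pos).
    """
    for cond in sheet.conditions:
        if not sheet.samples_of(cond):
            raise ValueError(f"condition {cond!r} has no samples")
    ordered = sorted(set((t, int(p)) for t, p in sites))
    idx = pd.MultiIndex.from_tuples(ordered, names=["target_id", "pos"])
    table = pd.DataFrame(index=idx)
    per_sample_rates = {}
    ref_col = None
    for sample_id in sorted(sample_pileups):
        frame = sample_pileups[sample_id].set_index(["target_id", "pos"])
        sub = frame.reindex(idx)
        rate = sub["error_rate"].to_numpy(float)
        rate = np.where(sub["coverage"].to_numpy(float) > 0, rate, np.nan)
        per_sample_rates[sample_id] = rate
        table[f"rate_{sample_id}"] = rate
        if ref_col is None:
            ref_col = sub["ref"]
    table.insert(0, "ref", ref_col)
    for cond in sheet.conditions:
        rates = np.column_stack(
            [per_sample_rates[s] for s in sheet.samples_of(cond)]
        )
        with np.errstate(invalid="ignore"):
            table[f"mean_{cond}"] = np.nanmean(rates, axis=1)
        table[f"n_{cond}"] = np.sum(~np.isnan(rates), axis=1)
    return table.reset_index()


@dataclass
class TargetAssignment:
    """Classification of one site against one KO condition."""

    target_id: str
    pos: int
    ko_condition: str
    status: str  # lost | retained | ambiguous
    wt_mean: float
    ko_mean: float
    fold_change: float
    ko_passes: int


def classify_sites(
    calls: ModificationCallSet,
    table: pd.DataFrame,
    sheet: SampleSheet,
    wt_condition: str,
    ko_conditions: Sequence[str],
    min_fold: float = 5.0,
) -> pd.DataFrame:
    """Classify every WT-called site as lost/retained/ambiguous per KO.

    A site enters the comparison when it passes in at least one WT sample.
    The KO mean error rate is floored at ``KO_RATE_FLOOR`` before the fold
    change so error-free KO sites do not blow up the ratio.
    """
    wt_samples = set(sheet.samples_of(wt_condition))
    if not wt_samples:
        raise ValueError(f"WT condition {wt_condition!r} not in sample sheet")
    indexed = table.set_index(["target_id", "pos"])
    rows = []
    for target_id, pos in calls.sites:
        passed = calls.passes_by_sample(target_id, pos)
        if not any(passed.get(s, False) for s in wt_samples):
            continue
        trow = indexed.loc[(target_id, pos)]
        wt_mean = float(trow[f"mean_{wt_condition}"])
        for ko in ko_conditions:
            ko_samples = sheet.samples_of(ko)
            ko_passes = sum(bool(passed.get(s, False)) for s in ko_samples)
            ko_mean = float(trow[f"mean_{ko}"])
            fold = wt_mean / max(ko_mean, KO_RATE_FLOOR)
            if ko_passes > 0:
                status = "retained"
            elif fold >= min_fold:
                status = "lost"
            else:
                status = "ambiguous"
            rows.append(
                {
                    "target_id": target_id,
                    "pos": pos,
                    "ko_condition": ko,
                    "status": status,
                    "wt_mean": wt_mean,
                    "ko_mean": ko_mean,
                    "fold_change": fold,
                    "ko_passes": ko_passes,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "target_id", "pos", "ko_condition", "status", "wt_mean",
            "ko_mean", "fold_change", "ko_passes",
        ],
    )


def write_report(
    table: pd.DataFrame, assignments: pd.DataFrame, outdir
) -> dict[str, Path]:
    """Write ``error_rates.tsv``, ``assignments.tsv`` and ``summary.txt``.

    Output is deterministic: fixed row order, fixed float formatting, so
    re-running on identical inputs reproduces the files byte for byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "error_rates": outdir / "error_rates.tsv",
        "assignments": outdir / "assignments.tsv",
        "summary": outdir / "summary.txt",
    }
    table.sort_values(["target_id", "pos"]).to_csv(
        paths["error_rates"], sep="\t", index=False, float_format="%.6g"
    )
    assignments.sort_values(["target_id", "pos", "ko_condition"]).to_csv(
        paths["assignments"], sep="\t", index=False, float_format="%.6g"
    )
    with open(paths["summary"], "w") as fh:
        fh.write("# sites per status and KO condition\n")
        if assignments.empty:
            fh.write("(no assignments)\n")
        else:
            counts = (
                assignments.groupby(["ko_condition", "status"])
                .size()
                .sort_index()
            )
            for (ko, status), n in counts.items():
                fh.write(f"{ko}\t{status}\t{n}\n")
    return paths
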