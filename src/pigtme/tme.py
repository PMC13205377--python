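"""Trait measurement error (TME) statistics and the comparison report.

TME for one animal at one occasion is the absolute difference between its
scale-measured and image-predicted body weight; the percentage form divides
by the scale BW.  The module also computes the rank-based GWAS agreement
statistic (how many of the top-k markers of a reference scan fall inside
the top-K of another scan) and assembles the per-experiment report:
goodness-of-fit per method and time point, the heritability triple
(scale BW, image BW, TME), agreement/TME-overlap counts, and the list of
animals with consistently extreme TME across time points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .quantgen import GWASResult

__all__ = ["TmeReport", "compute_tme", "tme_percent", "topk_agreement", "assemble_report"]


def _paired(scale_bw, image_bw) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(scale_bw, pd.Series) and isinstance(image_bw, pd.Series):
        if not scale_bw.index.equals(image_bw.index):
            raise ValueError("scale and image BW are not paired (index mismatch)")
    s = np.asarray(scale_bw, dtype=np.float64).ravel()
    i = np.asarray(image_bw, dtype=np.float64).ravel()
    if s.size != i.size:
        raise ValueError("scale and image BW lengths differ")
    return s, i


def compute_tme(scale_bw, image_bw) -> np.ndarray:
    """Element-wise |scale - image| in kg.  Symmetric in its arguments."""
    s, i = _paired(scale_bw, image_bw)
    return np.abs(s - i)


def tme_percent(scale_bw, image_bw) -> np.ndarray:
    """TME as a percentage of scale BW: 100 * |scale - image| / scale."""
    s, i = _paired(scale_bw, image_bw)
    if np.any(s <= 0):
        raise ValueError("scale BW must be positive for percentage TME")
    return 100.0 * np.abs(s - i) / s


def topk_agreement(
    rank_ref: GWASResult, rank_other: GWASResult, k_top: int = 10, k_ref: int = 100
) -> int:
    """|top-k_top markers of the reference scan ∩ top-k_ref of the other scan|.

    Both scans must cover the same marker universe; rankings come from the
    scans' own deterministic -log10(p) orderings.
    """
    ref_ids = set(rank_ref.table["marker_id"])
    other_ids = set(rank_other.table["marker_id"])
    if ref_ids != other_ids:
        raise ValueError("marker sets differ between the two scans")
    return len(set(rank_ref.top(k_top)) & set(rank_other.top(k_ref)))


@dataclass
class TmeReport:
    """The assembled four-table comparison report for one experiment.

    ``per_animal`` has one row per animal x time point x method with scale
    BW, image BW, TME and TME%; the three summary tables aggregate fit
    metrics, the heritability triple, and the top-marker agreement/overlap
    counts; ``consistency`` lists animals whose TME was in the top or
    bottom decile at two or more time points.  ``gaps`` names any stage
    whose output was missing when the report was assembled.
    """

    per_animal: pd.DataFrame
    fit_metrics: pd.DataFrame | None = None
    heritability: pd.DataFrame | None = None
    agreement: pd.DataFrame | None = None
    consistency: pd.DataFrame | None = None
    summary: pd.DataFrame | None = None
    gaps: list[str] = field(default_factory=list)

    def write(self, out_dir: str | Path) -> None:
        """Serialize all tables as TSV plus a JSON summary."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "per_animal": self.per_animal,
            "fit_metrics": self.fit_metrics,
            "heritability": self.heritability,
            "agreement": self.agreement,
            "consistency": self.consistency,
            "summary": self.summary,
        }
        for name, df in tables.items():
            if df is not None:
                df.to_csv(out / f"{name}.tsv", sep="\t", index=False, float_format="%.6g")
        meta = {"gaps": self.gaps, "tables": [k for k, v in tables.items() if v is not None]}
        (out / "report.json").write_text(json.dumps(meta, indent=2) + "\n")


def _consistency(per_animal: pd.DataFrame, decile: float, min_timepoints: int) -> pd.DataFrame:
    """Animals in the top/bottom TME decile at >= min_timepoints time points."""
    rows = []
    for method, g in per_animal.groupby("method", sort=True):
        flags: dict[str, dict[str, int]] = {}
        for _, tp_g in g.groupby("time_point", sort=True):
            hi = tp_g["tme"].quantile(1.0 - decile)
            lo = tp_g["tme"].quantile(decile)
            for _, r in tp_g.iterrows():
                d = flags.setdefault(r["animal_id"], {"high": 0, "low": 0})
                if r["tme"] >= hi:
                    d["high"] += 1
                if r["tme"] <= lo:
                    d["low"] += 1
        for aid, d in sorted(flags.items()):
            for group in ("high", "low"):
                if d[group] >= min_timepoints:
                    rows.append(
                        {"method": method, "animal_id": aid, "group": group, "n_timepoints": d[group]}
                    )
    return pd.DataFrame(rows, columns=["method", "animal_id", "group", "n_timepoints"])


def assemble_report(
    per_animal: pd.DataFrame,
    fit_metrics: pd.DataFrame | None = None,
    heritability: pd.DataFrame | None = None,
    agreement: pd.DataFrame | None = None,
    decile: float = 0.1,
    min_timepoints: int = 2,
) -> TmeReport:
    """Assemble the comparison report from stage outputs.

    ``per_animal`` must contain columns ``animal_id, time_point, method,
    scale_bw, image_bw``; TME columns are (re)computed here so the summary
    is always derivable from the raw rows.  Missing stage tables are
    recorded in ``gaps`` instead of failing.
    """
    required = {"animal_id", "time_point", "method", "scale_bw", "image_bw"}
    missing = required - set(per_animal.columns)
    if missing:
        raise ValueError(f"per_animal is missing column(s) {sorted(missing)}")
    pa = per_animal.copy()
    pa["tme"] = compute_tme(pa["scale_bw"].to_numpy(), pa["image_bw"].to_numpy())
    pa["tme_percent"] = tme_percent(pa["scale_bw"].to_numpy(), pa["image_bw"].to_numpy())
    summary = (
        pa.groupby(["method", "time_point"], sort=True)
        .agg(mean_tme=("tme", "mean"), mean_tme_percent=("tme_percent", "mean"), n=("tme", "size"))
        .reset_index()
    )
    gaps = [
        name
        for name, df in (
            ("fit_metrics", fit_metrics),
            ("heritability", heritability),
            ("agreement", agreement),
        )
        if df is None
    ]
    return TmeReport(
        per_animal=pa,
        fit_metrics=fit_metrics,
        heritability=heritability,
        agreement=agreement,
        consistency=_consistency(pa, decile, min_timepoints),
        summary=summary,
        gaps=gaps,
    )
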