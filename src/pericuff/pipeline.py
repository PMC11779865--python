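"""End-to-end orchestration: simulate or ingest, quantify, compare, report.

Two entry points mirror the two imaging procedures:

``run_roi_analysis`` builds a per-ROI table (phenotype counts,
pseudo-count log counts, inter-cell distance z-scores for configured
phenotype pairs, cuff detection and tissue-phenotype call, GTC category)
over a cohort of ROI frames.

``run_wholeslide_analysis`` computes per-sample corrected marker-density
fields, samples them at every cell, pools the values across samples into
equal-count bins, and tabulates bin composition by sample group.

Group comparisons use standard two-sided tests with Benjamini-Hochberg
adjustment across the declared family.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import __version__
from .config import config_hash, substream
from .core import CellMap, T_CELL_LABELS
from .density import bin_composition, per_cell_corrected_density, pooled_equal_count_bins
from .geometry import classify_roi_phenotype, detect_cuffs
from .point_pattern import zscore_matrix
from .scoring import gtc_category, gtc_class, log_transform_counts
from .simulate import TissueConfig, simulate_roi, simulate_tissue

__all__ = ["RunReport", "run_roi_analysis", "compare_groups", "run_wholeslide_analysis"]

DEFAULT_PAIRS = [
    ("CD4T", "CD4T"),
    ("CD8T", "CD8T"),
    ("CD4T", "CD8T"),
    ("CD8T", "CD4T"),
    ("TAM", "CD4T"),
    ("TAM", "CD8T"),
    ("TAM", "TAM"),
]


@dataclass
class RunReport:
    """Tidy result tables of one pipeline run plus its provenance."""

    roi_table: pd.DataFrame | None = None
    cuff_table: pd.DataFrame | None = None
    bin_table: pd.DataFrame | None = None
    comparison_table: pd.DataFrame | None = None
    per_cell_table: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)

    def write(self, out_dir) -> None:
        from pathlib import Path
        import json

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name in ("roi_table", "cuff_table", "bin_table", "comparison_table", "per_cell_table"):
            t = getattr(self, name)
            if t is not None:
                t.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False, float_format="%.10g")
        with open(out_dir / "run_metadata.json", "w") as fh:
            json.dump(self.metadata, fh, indent=2, default=str)


def _tissue_config(config: dict, seed: int) -> TissueConfig:
    fields = {k: v for k, v in config.get("tissue", {}).items()}
    return TissueConfig(seed=seed, **fields)


def run_roi_analysis(config: dict | None = None, seed: int = 0) -> RunReport:
    """Per-ROI analysis over a simulated cohort of ROI frames.

    Config keys (all optional): ``tissue`` (TissueConfig overrides),
    ``n_rois_per_phenotype`` (default 10), ``pairs`` (phenotype pairs for
    the z-score table), ``n_perm`` (default 1000), ``t_labels``.
    The cohort holds equal numbers of cuff, stromal_T and absent ROIs;
    everything is a pure function of (config, seed).
    """
    config = config or {}
    n_each = int(config.get("n_rois_per_phenotype", 10))
    if n_each < 1:
        raise ValueError("no ROIs requested")
    pairs = [tuple(p) for p in config.get("pairs", DEFAULT_PAIRS)]
    n_perm = int(config.get("n_perm", 1000))
    t_labels = tuple(config.get("t_labels", sorted(T_CELL_LABELS)))

    seeds = substream(seed, "roi_cohort").integers(0, 2**31 - 1, size=3 * n_each)
    rows = []
    cuff_rows = []
    idx = 0
    for true_phen in ("cuff", "stromal_T", "absent"):
        for rep in range(n_each):
            roi_seed = int(seeds[idx])
            idx += 1
            tcfg = _tissue_config(config, roi_seed)
            cells, vessels, membranes, frame, truth = simulate_roi(tcfg, true_phen)
            roi_id = f"{true_phen}_{rep}"
            cuffs = detect_cuffs(cells, membranes, t_labels=t_labels)
            call = classify_roi_phenotype(cells, cuffs, t_labels=t_labels)
            counts = cells.df["phenotype"].value_counts()
            malignant = counts.get("TumorCell", 0) + counts.get("GTC", 0)
            gtc_frac = counts.get("GTC", 0) / malignant if malignant else 0.0
            row = {
                "roi_id": roi_id,
                "true_phenotype": true_phen,
                "called_phenotype": call,
                "n_cells": len(cells),
                "n_cuffs": len(cuffs),
                "gtc_fraction": gtc_frac,
                "gtc_category": gtc_category(gtc_frac),
                "gtc_class": gtc_class(gtc_frac),
            }
            for label in ("TumorCell", "GTC", "TAM", "CD4T", "CD8T", "BCell", "Other"):
                c = int(counts.get(label, 0))
                row[f"n_{label}"] = c
                row[f"logcount_{label}"] = float(log_transform_counts(c))
            z = zscore_matrix(cells, pairs, n_perm=n_perm, seed=roi_seed)
            for r in z.itertuples(index=False):
                row[f"z_{r.from_type}_{r.to_type}"] = r.z
            rows.append(row)
            for ci, cuff in enumerate(cuffs):
                cuff_rows.append(
                    {
                        "roi_id": roi_id,
                        "cuff_id": f"{roi_id}_cuff{ci}",
                        "t_cell_count": cuff.t_cell_count,
                        "area_um2": cuff.area,
                        "equivalent_radius_um": cuff.equivalent_radius,
                        "size_class": cuff.size_class,
                    }
                )
    roi_table = pd.DataFrame(rows)
    cuff_table = pd.DataFrame(
        cuff_rows, columns=["roi_id", "cuff_id", "t_cell_count", "area_um2", "equivalent_radius_um", "size_class"]
    )
    meta = {"software": "pericuff", "version": __version__, "seed": seed, "config_hash": config_hash(config)}
    return RunReport(roi_table=roi_table, cuff_table=cuff_table, metadata=meta)


def compare_groups(
    values,
    groups,
    test: str = "ranksum",
    mtc: str = "bh",
) -> pd.DataFrame:
    """All pairwise group comparisons with BH adjustment across the family.

    ``test``: ``ranksum`` (two-sided Wilcoxon rank-sum, exact in small
    samples), ``ks`` (two-sample Kolmogorov-Smirnov) or ``chisq``
    (contingency of categorical values x groups, one global test).
    Degenerate contrasts (a group with no observations) are flagged, not
    dropped, and excluded from the adjustment family.
    """
    values = np.asarray(values)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups must have equal length")
    names = sorted(pd.unique(groups))
    if len(names) < 2:
        raise ValueError("need at least two groups")

    rows = []
    if test == "chisq":
        table = pd.crosstab(pd.Series(values, name="value"), pd.Series(groups, name="group"))
        chi2, p, dof, _ = stats.chi2_contingency(table)
        rows.append({"group_a": "all", "group_b": "all", "statistic": float(chi2), "p_raw": float(p), "flagged": False})
    else:
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                va = values[groups == a].astype(float)
                vb = values[groups == b].astype(float)
                va, vb = va[~np.isnan(va)], vb[~np.isnan(vb)]
                if len(va) == 0 or len(vb) == 0:
                    rows.append({"group_a": a, "group_b": b, "statistic": np.nan, "p_raw": np.nan, "flagged": True})
                    continue
                if test == "ranksum":
                    res = stats.mannwhitneyu(va, vb, alternative="two-sided", method="auto")
                elif test == "ks":
                    res = stats.ks_2samp(va, vb, alternative="two-sided")
                else:
                    raise ValueError(f"unknown test {test!r}")
                rows.append(
                    {"group_a": a, "group_b": b, "statistic": float(res.statistic), "p_raw": float(res.pvalue), "flagged": False}
                )
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    ok = ~out["flagged"] & out["p_raw"].notna()
    if ok.any():
        if mtc == "bh":
            out.loc[ok, "p_adj"] = multipletests(out.loc[ok, "p_raw"], method="fdr_bh")[1]
        elif mtc in (None, "none"):
            out.loc[ok, "p_adj"] = out.loc[ok, "p_raw"]
        else:
            raise ValueError(f"unknown mtc {mtc!r}")
    return out


def run_wholeslide_analysis(config: dict | None = None, seed: int = 0) -> RunReport:
    """Whole-sample corrected-density binning over a simulated cohort.

    Config keys: ``n_high`` / ``n_low`` (samples with and without the
    GTC gradient + TAM coupling; defaults 8 / 6), ``positive_labels``
    (marker-positive phenotypes for the density ratio, default GTC),
    ``sigma`` (KDE bandwidth, µm; default 150 at the synthetic sample
    scale), ``n_bins`` (default 20), ``tissue`` overrides, ``low_tissue``
    overrides for the flat group.  Each sample's ratio field uses that
    sample's own KDE; per-cell values are pooled before binning.
    """
    config = config or {}
    n_high = int(config.get("n_high", 8))
    n_low = int(config.get("n_low", 6))
    positive = tuple(config.get("positive_labels", ("GTC",)))
    sigma = float(config.get("sigma", 150.0))
    n_bins = int(config.get("n_bins", 20))
    t_labels = tuple(config.get("t_labels", sorted(T_CELL_LABELS)))
    phenos = tuple(config.get("phenotypes_of_interest", tuple(t_labels) + ("TAM",)))

    seeds = substream(seed, "wholeslide_cohort").integers(0, 2**31 - 1, size=n_high + n_low)
    frames = []
    groups: dict[str, str] = {}
    cuff_rows = []
    for k in range(n_high + n_low):
        group = "high" if k < n_high else "low"
        s = int(seeds[k])
        tcfg = _tissue_config(config, s)
        if group == "low":
            low_over = config.get(
                "low_tissue",
                {"gtc_peak": tcfg.gtc_floor, "tam_coupling": 0.0, "cuff_t_per_vessel": 0},
            )
            tcfg = replace(tcfg, **low_over)
        cells, vessels, membranes, truth = simulate_tissue(tcfg)
        sample_id = f"{group}_{k}"
        df = cells.df.copy()
        df["sample_id"] = sample_id
        df["cell_id"] = sample_id + "_" + df["cell_id"]
        cells = CellMap(df, cells.provenance)
        groups[sample_id] = group
        dens, defined = per_cell_corrected_density(cells, positive, sigma=sigma)
        d = cells.df.copy()
        d["density"] = np.where(defined, dens, np.nan)
        frames.append(d)
        for ci, cuff in enumerate(detect_cuffs(cells, membranes, t_labels=t_labels)):
            cuff_rows.append(
                {
                    "sample_id": sample_id,
                    "cuff_id": f"{sample_id}_cuff{ci}",
                    "t_cell_count": cuff.t_cell_count,
                    "area_um2": cuff.area,
                    "equivalent_radius_um": cuff.equivalent_radius,
                    "size_class": cuff.size_class,
                }
            )

    pooled = pd.concat(frames, ignore_index=True)
    all_cells = CellMap(pooled[list(CellMap.COLUMNS)])
    bin_ids = pooled_equal_count_bins(pooled["density"].to_numpy(), n_bins=n_bins)
    pooled["bin"] = bin_ids
    table = bin_composition(
        bin_ids, all_cells, phenotypes_of_interest=phenos,
        sample_groups=groups, densities=pooled["density"].to_numpy(),
    )
    meta = {
        "software": "pericuff",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config),
        "sample_groups": groups,
        "n_cells_pooled": int(len(pooled)),
        "n_cells_undefined_density": int(pooled["density"].isna().sum()),
    }
    return RunReport(
        bin_table=table,
        cuff_table=pd.DataFrame(
            cuff_rows,
            columns=["sample_id", "cuff_id", "t_cell_count", "area_um2", "equivalent_radius_um", "size_class"],
        ),
        per_cell_table=pooled[["cell_id", "sample_id", "phenotype", "x", "y", "density", "bin"]],
        metadata=meta,
    )
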