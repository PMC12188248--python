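"""Group statistics and report rendering.

The unit of replication is the fly: events are averaged to one value per
fly per group before any test.  Groups are compared with a one-way ANOVA on
the per-fly means; pairwise comparisons are two-group ANOVAs (identical to
pooled-variance t-tests, F = t^2) with Bonferroni multiplication over the
pairs within the contrast.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

__all__ = [
    "GroupComparison",
    "InsufficientDataError",
    "flywise_means",
    "omnibus_test",
    "compare_groups",
    "box_stats",
    "build_report",
]

log = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    pass


@dataclass
class GroupComparison:
    contrast: str
    region: str | None
    means: pd.DataFrame  # columns: fly_id, group, mean
    n_flies: int
    f_stat: float
    p_value: float
    pairwise: pd.DataFrame  # group_a, group_b, p_raw, p_bonferroni, significant
    alpha: float = 0.05
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)

    def summary(self) -> pd.DataFrame:
        rows = [{
            "contrast": self.contrast, "region": self.region, "test": "omnibus",
            "group_a": "all", "group_b": "all", "n_flies": self.n_flies,
            "F": self.f_stat, "p": self.p_value, "significant": self.significant,
        }]
        for _, r in self.pairwise.iterrows():
            rows.append({
                "contrast": self.contrast, "region": self.region, "test": "pairwise",
                "group_a": r.group_a, "group_b": r.group_b, "n_flies": self.n_flies,
                "F": np.nan, "p": r.p_bonferroni, "significant": bool(r.significant),
            })
        return pd.DataFrame(rows)


def flywise_means(
    records: pd.DataFrame, value_col: str = "amp_corrected"
) -> pd.DataFrame:
    """One mean per fly per group; flies with an empty group cell are dropped.

    Expects the output of :func:`flyssvep.ssvep.corrected_amplitude` (a
    ``group`` column); raises when fewer than two flies survive.
    """
    if "group" not in records.columns:
        raise ValueError("records need a 'group' column (run corrected_amplitude first)")
    means = (
        records.groupby(["fly_id", "group"], sort=False)[value_col]
        .mean()
        .reset_index()
        .rename(columns={value_col: "mean"})
    )
    n_groups = records["group"].nunique()
    counts = means.groupby("fly_id").size()
    complete = counts[counts == n_groups].index
    dropped = sorted(set(means["fly_id"]) - set(complete))
    if dropped:
        log.info("flywise_means: dropping flies with empty cells: %s", dropped)
    means = means[means["fly_id"].isin(complete)]
    if means["fly_id"].nunique() < 2:
        raise InsufficientDataError("fewer than 2 flies with complete data")
    return means.reset_index(drop=True)


def _anova(groups: list[np.ndarray]) -> tuple[float, float, bool]:
    """One-way ANOVA F and p; handles the zero-variance degenerate case."""
    allvals = np.concatenate(groups)
    if np.allclose(allvals.var(), 0.0):
        return 0.0, 1.0, True
    within_var = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if within_var == 0.0:
        # perfect separation: report p below machine floor
        log.warning("omnibus_test: zero within-group variance; exact-equality fallback")
        equal_means = len({float(g.mean()) for g in groups}) == 1
        return (0.0, 1.0, True) if equal_means else (np.inf, 0.0, True)
    f, p = sp_stats.f_oneway(*groups)
    return float(f), float(p), False


def omnibus_test(
    means: pd.DataFrame,
    contrast: str = "",
    region: str | None = None,
    alpha: float = 0.05,
    pairs: list[tuple[str, str]] | None = None,
) -> GroupComparison:
    """One-way ANOVA across groups on per-fly means, plus Bonferroni pairs.

    ``pairs`` restricts the pairwise family (e.g. within-group comparisons
    only); default is all pairwise combinations.  The Bonferroni-corrected
    p is min(1, raw p x number of pairs in the family).
    """
    labels = list(means["group"].unique())
    if len(labels) < 2:
        raise InsufficientDataError("need >= 2 groups")
    arrays = [means.loc[means["group"] == g, "mean"].to_numpy(dtype=float) for g in labels]
    if any(len(a) < 2 for a in arrays):
        raise InsufficientDataError("need >= 2 flies per group")
    f, p, degenerate = _anova(arrays)

    if pairs is None:
        pairs = list(itertools.combinations(labels, 2))
    n_comp = len(pairs)
    rows = []
    for ga, gb in pairs:
        a = means.loc[means["group"] == ga, "mean"].to_numpy(dtype=float)
        b = means.loc[means["group"] == gb, "mean"].to_numpy(dtype=float)
        fp, pp, _ = _anova([a, b])
        p_bonf = min(1.0, pp * n_comp)
        rows.append({
            "group_a": ga, "group_b": gb, "p_raw": pp,
            "p_bonferroni": p_bonf, "significant": p_bonf < alpha,
        })
    return GroupComparison(
        contrast=contrast, region=region, means=means,
        n_flies=int(means["fly_id"].nunique()), f_stat=f, p_value=p,
        pairwise=pd.DataFrame(rows), alpha=alpha, degenerate=degenerate,
    )


def compare_groups(
    corrected: pd.DataFrame,
    contrast: str,
    region: str | None = None,
    alpha: float = 0.05,
    pairs: list[tuple[str, str]] | None = None,
) -> GroupComparison:
    """Convenience: per-fly means then omnibus test on a corrected table."""
    return omnibus_test(flywise_means(corrected), contrast=contrast,
                        region=region, alpha=alpha, pairs=pairs)


def box_stats(values) -> dict:
    """Box-plot summary: median, quartiles and 1.5x IQR whisker limits."""
    v = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    return {
        "median": float(med), "q1": float(q1), "q3": float(q3),
        "whisker_low": float(q1 - 1.5 * iqr), "whisker_high": float(q3 + 1.5 * iqr),
        "n": int(v.size),
    }


def build_report(
    comparisons: list[GroupComparison],
    out_dir,
    spectra: pd.DataFrame | None = None,
    bouts: pd.DataFrame | None = None,
    manifest: dict | None = None,
    figures: bool = True,
) -> Path:
    """Render comparisons, spectra and bout tables into a report directory.

    Writes comparisons.csv (test results), group_stats.csv (box-plot
    summaries per group), optional spectra.csv / bouts.csv, figures and a
    run manifest.  Sections without data are omitted with a note.
    """
    if not comparisons:
        raise ValueError("at least one comparison is required")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    notes = []

    pd.concat([c.summary() for c in comparisons], ignore_index=True).to_csv(
        out / "comparisons.csv", index=False
    )
    rows = []
    for c in comparisons:
        for g, sub in c.means.groupby("group", sort=False):
            rows.append({"contrast": c.contrast, "region": c.region, "group": g,
                         **box_stats(sub["mean"])})
    pd.DataFrame(rows).to_csv(out / "group_stats.csv", index=False)

    if spectra is not None and len(spectra):
        spectra.to_csv(out / "spectra.csv", index=False)
    else:
        notes.append("no spectra provided; spectral section omitted")
    if bouts is not None and len(bouts):
        bouts.to_csv(out / "bouts.csv", index=False)
    else:
        notes.append("no bout table provided; bout section omitted")

    if figures:
        _render_figures(comparisons, spectra, bouts, out / "figures")

    (out / "manifest.json").write_text(json.dumps({
        "n_comparisons": len(comparisons),
        "contrasts": [c.contrast for c in comparisons],
        "notes": notes,
        **(manifest or {}),
    }, indent=2))
    return out


def _render_figures(comparisons, spectra, bouts, fig_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir.mkdir(parents=True, exist_ok=True)
    for c in comparisons:
        fig, ax = plt.subplots(figsize=(4, 3))
        groups = list(c.means["group"].unique())
        data = [c.means.loc[c.means["group"] == g, "mean"] for g in groups]
        ax.boxplot(data, tick_labels=groups, whis=1.5)
        ax.set_ylabel("corrected amplitude")
        ax.set_title(f"{c.contrast}" + (f" ({c.region})" if c.region else "")
                     + f"  p={c.p_value:.3g}")
        fig.tight_layout()
        safe = c.contrast.replace("/", "_") + (f"_{c.region}" if c.region else "")
        fig.savefig(fig_dir / f"{safe}.png", dpi=100)
        plt.close(fig)
    if spectra is not None and len(spectra):
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.semilogy(spectra["freq_hz"], spectra["power"])
        ax.set_xlim(0, 20)
        ax.set_xlabel("frequency (Hz)")
        ax.set_ylabel("normalized power")
        fig.tight_layout()
        fig.savefig(fig_dir / "spectrum.png", dpi=100)
        plt.close(fig)
    if bouts is not None and len(bouts):
        fig, ax = plt.subplots(figsize=(4, 3))
        for state, color in (("wake", "tab:red"), ("sleep", "tab:blue")):
            d = bouts.loc[bouts["state"] == state]
            if len(d):
                dur = (d["end_s"] - d["start_s"]) / 60.0
                ax.hist(dur, bins=20, alpha=0.5, label=state, color=color)
        ax.set_xlabel("bout duration (min)")
        ax.set_ylabel("count")
        ax.legend()
        fig.tight_layout()
        fig.savefig(fig_dir / "bout_durations.png", dpi=100)
        plt.close(fig)
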