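"""Group-level aggregation of per-contact decoding results.

Three population summaries are produced: counts of significant contacts
per stimulus format (and the intersection significant in all four),
per-region accuracy maps over significant contacts, and time-frequency
feature maps giving at each (frequency, time) point the proportion of
contacts with a covering significant cluster, the fraction of those whose
covering cluster is positive (directionality), and the mean accuracy of
the covering contacts (classification value).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .clusterstats import ClusterSet
from .synth import MODALITIES


def _results_frame(results: Iterable) -> pd.DataFrame:
    rows = [
        {
            "contact": r.contact,
            "format": r.format,
            "accuracy": r.accuracy,
            "p_value": r.p_value,
            "significant": bool(r.significant),
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    if len(df) and df.duplicated(["contact", "format"]).any():
        raise ValueError("duplicate (contact, format) results")
    return df


def count_significant(results: Iterable) -> dict[str, int]:
    """Per-format significant-contact counts plus the all-format intersection.

    The intersection counts contacts significant in every one of the four
    stimulus modalities (the pooled "all" contrast is reported separately).
    """
    df = _results_frame(results)
    counts: dict[str, int] = {}
    for fmt in MODALITIES + ("all",):
        sub = df[df["format"] == fmt] if len(df) else df
        counts[fmt] = int(sub["significant"].sum()) if len(sub) else 0
    if len(df):
        sig = df[df["significant"] & df["format"].isin(MODALITIES)]
        per_contact = sig.groupby("contact")["format"].nunique()
        counts["intersection"] = int((per_contact == len(MODALITIES)).sum())
    else:
        counts["intersection"] = 0
    return counts


@dataclass
class RegionAccuracyMap:
    """Region label -> (aggregate accuracy, n_contacts, n_significant).

    Regions with no significant contact are omitted; the aggregate is taken
    over significant contacts only.
    """

    entries: dict[str, tuple[float, int, int]]
    aggregate: str = "max"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "region": region,
                    "accuracy": acc,
                    "n_contacts": n,
                    "n_significant": ns,
                }
                for region, (acc, n, ns) in sorted(self.entries.items())
            ]
        )


def region_accuracy(
    results: Iterable,
    electrodes: pd.DataFrame,
    aggregate: str = "max",
) -> RegionAccuracyMap:
    """Aggregate significant-contact accuracies by anatomical region."""
    if aggregate not in ("max", "mean"):
        raise ValueError("aggregate must be 'max' or 'mean'")
    df = _results_frame(results)
    region_of = dict(zip(electrodes["name"], electrodes["region"]))
    missing = set(df["contact"]) - set(region_of) if len(df) else set()
    if missing:
        raise ValueError(f"contacts without a region label: {sorted(missing)}")
    entries: dict[str, tuple[float, int, int]] = {}
    if not len(df):
        return RegionAccuracyMap(entries=entries, aggregate=aggregate)
    df = df.assign(region=df["contact"].map(region_of))
    for region, sub in df.groupby("region"):
        sig = sub[sub["significant"]]
        if not len(sig):
            continue
        acc = float(sig["accuracy"].max() if aggregate == "max" else sig["accuracy"].mean())
        entries[str(region)] = (acc, int(len(sub)), int(len(sig)))
    return RegionAccuracyMap(entries=entries, aggregate=aggregate)


@dataclass
class FeatureMapBundle:
    """Three group-level grids over (frequency+voltage, time) feature space.

    ``proportion_significant`` is defined everywhere; ``proportion_positive``
    and ``classification_value`` are NaN-masked where no significant cluster
    of any contact covers the point.
    """

    proportion_significant: np.ndarray
    proportion_positive: np.ndarray
    classification_value: np.ndarray
    n_contacts: int
    format: str = "all"
    freqs_hz: np.ndarray | None = None
    times: np.ndarray | None = None


def feature_maps(
    results_and_clusters: Sequence[tuple[object, ClusterSet | None]],
    format: str = "all",
    n_analyzed: int | None = None,
) -> FeatureMapBundle:
    """Build the three feature maps for one stimulus format.

    ``results_and_clusters`` pairs each analyzed contact's decoding result
    with its ClusterSet (None when the contact was not significant).  At
    each grid point: the proportion of analyzed contacts whose significant
    clusters cover it; among covering contacts, the fraction whose covering
    cluster is positive; and the mean accuracy of covering contacts.
    """
    shape = None
    for _, cs in results_and_clusters:
        if cs is not None:
            if shape is None:
                shape = cs.t_map.shape
            elif cs.t_map.shape != shape:
                raise ValueError("cluster masks have mismatched feature-space shapes")
    n_total = n_analyzed if n_analyzed is not None else len(results_and_clusters)
    if shape is None:
        raise ValueError("no cluster sets provided; feature maps undefined")
    covering = np.zeros(shape)
    positive = np.zeros(shape)
    acc_sum = np.zeros(shape)
    for res, cs in results_and_clusters:
        if cs is None:
            continue
        pos = cs.significant_mask(sign=+1)
        neg = cs.significant_mask(sign=-1)
        any_mask = pos | neg
        covering += any_mask
        positive += pos
        acc_sum += any_mask * float(res.accuracy)
    with np.errstate(invalid="ignore", divide="ignore"):
        prop_sig = covering / max(n_total, 1)
        prop_pos = np.where(covering > 0, positive / np.maximum(covering, 1), np.nan)
        cls_val = np.where(covering > 0, acc_sum / np.maximum(covering, 1), np.nan)
    return FeatureMapBundle(
        proportion_significant=prop_sig,
        proportion_positive=prop_pos,
        classification_value=cls_val,
        n_contacts=n_total,
        format=format,
    )


def plot_feature_maps(bundle: FeatureMapBundle, path=None):
    """Three-row rendering (proportion / directionality / classification
    value) of a feature-map bundle; returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grids = [
        ("proportion significant", bundle.proportion_significant, "viridis"),
        ("proportion positive", bundle.proportion_positive, "viridis"),
        ("classification value", bundle.classification_value, "viridis"),
    ]
    fig, axes = plt.subplots(3, 1, figsize=(6, 9), constrained_layout=True)
    for ax, (title, grid, cmap) in zip(axes, grids):
        im = ax.imshow(grid, aspect="auto", origin="lower", cmap=cmap)
        ax.set_title(f"{title} ({bundle.format})")
        ax.set_xlabel("time bin")
        ax.set_ylabel("frequency row")
        fig.colorbar(im, ax=ax)
    if path is not None:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig
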