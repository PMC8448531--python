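"""Synaptic-bouton QC and soma-proximity contact counting.

Genetically labelled boutons are validated against an independent synaptic
marker (synaptotagmin): the syn-negative boutons are typically small, so a
volume floor (0.07 µm³, inclusive) screens out non-synaptic puncta before
any mapping. Contacts between terminals and target neurons use a
centre-distance criterion — a terminal contacts a soma when its distance to
the soma centre is within radius + tolerance (somata are treated as disks
by their measured diameter).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import FormatError, ValidationError
from .io import PointTable
from .stats import summarize, welch_t_test

__all__ = [
    "FilterResult",
    "ContactReport",
    "filter_boutons",
    "syn_positive_fraction",
    "count_contacts",
    "compare_contact_groups",
]


@dataclasses.dataclass
class FilterResult:
    retained: PointTable
    n_retained: int
    n_excluded: int
    threshold: float


def filter_boutons(
    boutons: PointTable, volume_threshold: float = 0.07
) -> FilterResult:
    """Retain boutons with volume >= threshold (inclusive boundary)."""
    if "volume" not in boutons.data.columns:
        raise FormatError("bouton table has no 'volume' column")
    keep = boutons.data["volume"].to_numpy(float) >= volume_threshold
    retained = PointTable(
        data=boutons.data.loc[keep].reset_index(drop=True),
        section_id=boutons.section_id,
        side=boutons.side,
    )
    return FilterResult(
        retained=retained,
        n_retained=int(keep.sum()),
        n_excluded=int((~keep).sum()),
        threshold=float(volume_threshold),
    )


def syn_positive_fraction(boutons: PointTable) -> tuple[float, int, int]:
    """Fraction of boutons carrying the syn-positive flag, with raw counts.

    Returns ``(fraction, n_positive, n_total)``; an empty set returns a NaN
    fraction.
    """
    if "syn_positive" not in boutons.data.columns:
        raise FormatError("bouton table has no 'syn_positive' column")
    n = len(boutons)
    if n == 0:
        return float("nan"), 0, 0
    pos = int(boutons.data["syn_positive"].astype(bool).sum())
    return pos / n, pos, n


@dataclasses.dataclass
class ContactReport:
    """Per-target contact counts with optional group labels."""

    counts: pd.DataFrame  # target index, contact count, group

    def by_group(self) -> dict[str, np.ndarray]:
        if "group" not in self.counts.columns:
            return {"all": self.counts["contacts"].to_numpy(float)}
        return {
            str(g): grp["contacts"].to_numpy(float)
            for g, grp in self.counts.groupby("group")
        }


def count_contacts(
    targets: PointTable,
    terminals: PointTable,
    tolerance: float = 1.0,
    group_col: str | None = None,
) -> ContactReport:
    """Count terminals within radius + tolerance of each target centre.

    A terminal may contact several targets. Target radii come from the
    ``diameter`` column (radius = diameter / 2); both tables must share a
    coordinate frame (checked only by unit metadata).
    """
    if "diameter" not in targets.data.columns:
        raise FormatError("target table has no 'diameter' column")
    if targets.units != terminals.units:
        raise ValidationError("targets and terminals are in different coordinate frames")
    term_xy = terminals.xy
    tree = cKDTree(term_xy) if len(term_xy) else None
    rows = []
    for i, (x, y) in enumerate(targets.xy):
        radius = float(targets.data["diameter"].iloc[i]) / 2.0
        n = len(tree.query_ball_point([x, y], radius + tolerance)) if tree else 0
        row = {"target": i, "contacts": n}
        if group_col is not None:
            row["group"] = targets.data[group_col].iloc[i]
        rows.append(row)
    return ContactReport(counts=pd.DataFrame(rows))


def compare_contact_groups(
    report: ContactReport, group_a: str, group_b: str
) -> dict[str, float]:
    """Welch comparison of per-neuron contact counts between two groups.

    Returns group means ± population SDs plus the Welch t, df and p.
    """
    groups = report.by_group()
    for g in (group_a, group_b):
        if g not in groups:
            raise ValidationError(f"group {g!r} not present in report")
    a, b = groups[group_a], groups[group_b]
    mean_a, sd_a = summarize(a)
    mean_b, sd_b = summarize(b)
    t, df, p = welch_t_test(a, b)
    return {
        f"mean_{group_a}": mean_a, f"sd_{group_a}": sd_a,
        f"mean_{group_b}": mean_b, f"sd_{group_b}": sd_b,
        "t": t, "df": df, "p": p,
    }
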