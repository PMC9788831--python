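"""Per-microtubule transition counting and per-condition summaries.

Aggregates ordered segment calls into lattice-type transitions (seam-count
changes, one-protofilament seam offsets, N_S changes) and pools
microtubules into condition tables: totals of segments, lateral
interactions, A/B/ND contacts and transitions, plus two frequency
conventions - the aggregate ratio (total transitions / total length) and
the per-microtubule mean +/- SD of individual frequencies. Both are
reported because they answer different questions and differ on heterogeneous
data sets. Conditions are compared with the Wilcoxon-Mann-Whitney rank-sum
test (exact by enumeration for small samples, normal approximation with tie
correction otherwise).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb, erf, sqrt

import numpy as np
import pandas as pd

from .caller import SegmentCall

__all__ = ["Transition", "MicrotubuleResult", "ConditionSummary",
           "count_transitions", "lateral_interaction_count",
           "condition_summary", "ranksum_test"]


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class Transition:
    """Change of lattice organization between two determined segments."""

    between: tuple[int, int]  # segment indices bracketing the change
    kind: str  # seam-count | seam-offset | N_S-change
    before: frozenset[int]
    after: frozenset[int]


def _is_offset_by_one(a: frozenset[int], b: frozenset[int], n: int) -> bool:
    """True when b is a with exactly one seam moved to an adjacent contact."""
    if len(a) != len(b):
        return False
    diff = a.symmetric_difference(b)
    if len(diff) != 2:
        return False
    i, j = sorted(diff)
    return (j - i) % n in (1, n - 1)


def count_transitions(calls: list[SegmentCall]) -> list[Transition]:
    """Transitions between consecutive determined segments.

    Segments containing ND contacts carry no seam set; they are bridged, and
    a change between their determined neighbours is localized to the bridged
    interval (finer re-segmentation would refine it). With fewer than two
    determined segments the list is empty.
    """
    if len(calls) < 2:
        return []
    determined = [(i, c) for i, c in enumerate(calls) if c.determined]
    out: list[Transition] = []
    for (i, a), (j, b) in zip(determined[:-1], determined[1:]):
        if a.N != b.N or a.S != b.S:
            out.append(Transition((i, j), "N_S-change", a.seam_set, b.seam_set))
        elif a.seam_set != b.seam_set:
            kind = ("seam-offset" if _is_offset_by_one(a.seam_set, b.seam_set, a.N)
                    else "seam-count")
            out.append(Transition((i, j), kind, a.seam_set, b.seam_set))
    return out


def lateral_interaction_count(calls: list[SegmentCall]) -> int:
    """Total lateral contacts: each closed segment ring contributes its N."""
    return sum(c.N for c in calls if c.N is not None)


@dataclass(frozen=True)
class MicrotubuleResult:
    """Ordered segment calls of one microtubule plus derived counts."""

    mt_id: str
    length_um: float
    calls: list[SegmentCall]
    transitions: list[Transition] = field(default_factory=list)

    @classmethod
    def from_calls(cls, mt_id: str, length_um: float,
                   calls: list[SegmentCall]) -> "MicrotubuleResult":
        return cls(mt_id=mt_id, length_um=length_um, calls=calls,
                   transitions=count_transitions(calls))

    @property
    def frequency(self) -> float:
        if self.length_um <= 0:
            raise StatsError(f"microtubule {self.mt_id} has non-positive length")
        return len(self.transitions) / self.length_um

    def contact_counts(self) -> dict:
        a = b = nd = 0
        for c in self.calls:
            if c.contact_types is None:
                if c.N:
                    nd += c.N
                continue
            a += int(np.sum(c.contact_types == "A"))
            b += int(np.sum(c.contact_types == "B"))
            nd += int(np.sum(c.contact_types == "N"))
        return {"A": a, "B": b, "ND": nd}

    def to_dict(self) -> dict:
        return {
            "mt_id": self.mt_id,
            "length_um": self.length_um,
            "segments": [c.to_dict() for c in self.calls],
            "transitions": [
                {"between": list(t.between), "kind": t.kind,
                 "before": sorted(t.before or []), "after": sorted(t.after or [])}
                for t in self.transitions
            ],
            "frequency_per_um": self.frequency,
        }


@dataclass(frozen=True)
class ConditionSummary:
    """Pooled statistics of one assembly condition."""

    label: str
    n_microtubules: int
    total_length_um: float
    n_segments: int
    lateral_interactions: int
    counts: dict  # A / B / ND
    n_transitions: int
    aggregate_frequency: float  # total transitions / total length
    per_mt_mean: float
    per_mt_sd: float
    ns_percent: dict
    seam_number_percent: dict
    lattice_type_percent: dict

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("Microtubules", self.n_microtubules),
            ("Total length (um)", round(self.total_length_um, 2)),
            ("Segments", self.n_segments),
            ("Lateral interactions", self.lateral_interactions),
            ("A-type", self.counts["A"]),
            ("B-type", self.counts["B"]),
            ("ND", self.counts["ND"]),
            ("Lattice-type transitions", self.n_transitions),
            ("Aggregate frequency (um^-1)", round(self.aggregate_frequency, 2)),
            ("Per-MT frequency mean (um^-1)", round(self.per_mt_mean, 2)),
            ("Per-MT frequency SD (um^-1)", round(self.per_mt_sd, 2)),
        ]
        return pd.DataFrame(rows, columns=["quantity", self.label])


def condition_summary(results: list[MicrotubuleResult],
                      label: str = "condition") -> ConditionSummary:
    """Pool microtubule results into a condition table.

    The aggregate frequency is total transitions over total length; the
    per-microtubule mean +/- SD averages individual frequencies (these
    differ whenever lengths are heterogeneous).
    """
    if not results:
        raise StatsError("condition_summary requires at least one microtubule")
    total_len = sum(r.length_um for r in results)
    n_trans = sum(len(r.transitions) for r in results)
    freqs = np.array([r.frequency for r in results])
    counts = {"A": 0, "B": 0, "ND": 0}
    for r in results:
        for k, v in r.contact_counts().items():
            counts[k] += v
    n_segments = sum(len(r.calls) for r in results)
    lat = sum(lateral_interaction_count(r.calls) for r in results)

    ns_counter: dict[str, int] = {}
    seam_counter: dict[int, int] = {}
    for r in results:
        for c in r.calls:
            if c.N is not None and c.S is not None:
                key = f"{c.N}_{c.S}"
                ns_counter[key] = ns_counter.get(key, 0) + 1
            if c.determined:
                ns = len(c.seam_set)
                seam_counter[ns] = seam_counter.get(ns, 0) + 1
    n_ns = sum(ns_counter.values())
    n_seam = sum(seam_counter.values())
    ns_percent = {k: 100.0 * v / n_ns for k, v in sorted(ns_counter.items())} if n_ns else {}
    seam_percent = {k: 100.0 * v / n_seam
                    for k, v in sorted(seam_counter.items())} if n_seam else {}
    lt_percent = ({k: 100.0 * v / lat for k, v in counts.items()} if lat else {})

    return ConditionSummary(
        label=label,
        n_microtubules=len(results),
        total_length_um=total_len,
        n_segments=n_segments,
        lateral_interactions=lat,
        counts=counts,
        n_transitions=n_trans,
        aggregate_frequency=n_trans / total_len if total_len > 0 else 0.0,
        per_mt_mean=float(freqs.mean()),
        per_mt_sd=float(freqs.std(ddof=1)) if len(freqs) > 1 else 0.0,
        ns_percent=ns_percent,
        seam_number_percent=seam_percent,
        lattice_type_percent=lt_percent,
    )


def plot_condition_panels(summaries: list[ConditionSummary], path=None):
    """Bar panels per condition: lattice-type %, N_S %, seam number %, and
    transition frequency. Returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 4, figsize=(14, 3.2))
    labels = [s.label for s in summaries]
    panels = [
        ("Lattice type (%)", [s.lattice_type_percent for s in summaries]),
        ("N_S class (%)", [s.ns_percent for s in summaries]),
        ("Seam number (%)", [s.seam_number_percent for s in summaries]),
    ]
    for ax, (title, dicts) in zip(axes[:3], panels):
        keys = sorted({k for d in dicts for k in d}, key=str)
        width = 0.8 / max(1, len(summaries))
        for i, (lab, d) in enumerate(zip(labels, dicts)):
            x = np.arange(len(keys)) + i * width
            ax.bar(x, [d.get(k, 0.0) for k in keys], width=width, label=lab)
        ax.set_xticks(np.arange(len(keys)) + 0.4 - width / 2)
        ax.set_xticklabels([str(k) for k in keys], rotation=45)
        ax.set_title(title)
    ax = axes[3]
    ax.bar(labels, [s.aggregate_frequency for s in summaries])
    ax.set_title("Transition frequency (um$^{-1}$)")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    sv = values[order]
    while i < len(sv):
        j = i
        while j + 1 < len(sv) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def ranksum_test(sample_a, sample_b, exact_limit: int = 12) -> tuple[float, float]:
    """Wilcoxon-Mann-Whitney rank-sum test with midrank ties.

    Returns (U of sample_a, two-sided p). The p-value is exact - computed by
    enumerating every assignment of the pooled midranks to group a - when
    n_a + n_b <= ``exact_limit``; larger samples use the normal
    approximation with the tie-corrected variance.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise StatsError("both samples must be non-empty")
    na, nb = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    ra = ranks[:na].sum()
    u_a = ra - na * (na + 1) / 2.0

    if na + nb <= exact_limit:
        # enumerate all C(na+nb, na) assignments of midranks to group a
        total = comb(na + nb, na)
        count_extreme = 0
        mean_u = na * nb / 2.0
        obs_dev = abs(u_a - mean_u)
        for combo in itertools.combinations(range(na + nb), na):
            u = ranks[list(combo)].sum() - na * (na + 1) / 2.0
            if abs(u - mean_u) >= obs_dev - 1e-9:
                count_extreme += 1
        p = count_extreme / total
        return float(u_a), float(min(1.0, p))

    # normal approximation with tie correction
    n = na + nb
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts)
    var_u = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u == 0:
        return float(u_a), 1.0
    z = (u_a - na * nb / 2.0) / sqrt(var_u)
    p = 2.0 * (1.0 - 0.5 * (1.0 + erf(abs(z) / sqrt(2.0))))
    return float(u_a), float(min(1.0, p))
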