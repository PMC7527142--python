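"""Sample-discriminatory marker-SNP identification and pairwise sharing.

Marker-SNPs are (site, allele) calls unique to one sample within a pool
holding one sample per individual; they fingerprint the strain an
individual carried at the pool timepoint. When the remaining samples are
added back, the fraction of marker-SNPs shared between two samples tracks
whether they carry the same strain.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from syntrack.simulate import VariantTable

logger = logging.getLogger(__name__)


@dataclass
class MarkerSNPSet:
    sample_id: str
    markers: frozenset[tuple[str, str]]  # (site_id, allele)


@dataclass
class SharingResult:
    sample_a: str
    sample_b: str
    shared: int
    total: int

    @property
    def percent_shared(self) -> float | None:
        """100 x |A n B| / |A u B|; ``None`` (undefined) when the union is empty."""
        if self.total == 0:
            return None
        return 100.0 * self.shared / self.total


def identify_marker_snps(
    variants: VariantTable, pool: dict[str, str] | list[str]
) -> dict[str, MarkerSNPSet]:
    """Marker-SNPs per pool sample: alleles unique within the pool.

    ``pool`` maps individual_id -> sample_id (or is a list of sample ids
    already known to be one per individual). A marker for pool sample s is
    a (site, allele) where s's call differs from every OTHER pool sample's
    call at that site; missing calls elsewhere do not veto uniqueness.
    """
    if isinstance(pool, dict):
        sample_ids = list(pool.values())
        if len(set(pool.keys())) != len(sample_ids):
            raise ValueError("duplicate individual in pool")
    else:
        sample_ids = list(pool)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample in pool")
    for s in sample_ids:
        if s not in variants.calls:
            raise ValueError(f"pool sample {s} absent from variant table")
    out = {}
    for s in sample_ids:
        markers = set()
        for site, allele in variants.calls[s].items():
            unique = True
            for other in sample_ids:
                if other == s:
                    continue
                if variants.calls[other].get(site) == allele:
                    unique = False
                    break
            if unique:
                markers.add((site, allele))
        out[s] = MarkerSNPSet(s, frozenset(markers))
    return out


def evaluate_markers_in_sample(
    variants: VariantTable, marker_pool: set[tuple[str, str]], sample_id: str
) -> frozenset[tuple[str, str]]:
    """Markers from the pooled marker list observed in a sample's own calls."""
    calls = variants.calls[sample_id]
    return frozenset(
        (site, allele) for site, allele in marker_pool if calls.get(site) == allele
    )


def percent_shared(markers_a: frozenset | MarkerSNPSet, markers_b) -> SharingResult:
    """Shared fraction of two evaluated marker sets (union denominator)."""
    a = markers_a.markers if isinstance(markers_a, MarkerSNPSet) else frozenset(markers_a)
    b = markers_b.markers if isinstance(markers_b, MarkerSNPSet) else frozenset(markers_b)
    name_a = markers_a.sample_id if isinstance(markers_a, MarkerSNPSet) else ""
    name_b = markers_b.sample_id if isinstance(markers_b, MarkerSNPSet) else ""
    shared = len(a & b)
    total = len(a | b)
    return SharingResult(name_a, name_b, shared, total)


def sharing_table(
    variants: VariantTable,
    metadata: pd.DataFrame,
    denominator: str = "union",
) -> pd.DataFrame:
    """All-pairs percent-shared marker-SNPs for a cohort.

    The pool takes each individual's first timepoint; the remaining samples
    are then added back and every sample's marker set is evaluated against
    its own calls before the pairwise comparison. ``denominator`` is
    ``union`` (|A u B|, default) or ``sum`` (|A| + |B|).
    """
    if denominator not in ("union", "sum"):
        raise ValueError("denominator must be 'union' or 'sum'")
    first = metadata.sort_values(["individual_id", "timepoint"]).groupby(
        "individual_id", sort=True
    ).head(1)
    pool = dict(zip(first["individual_id"], first["sample_id"]))
    marker_sets = identify_marker_snps(variants, pool)
    marker_pool = set().union(*(m.markers for m in marker_sets.values())) if marker_sets else set()
    samples = sorted(metadata["sample_id"])
    evaluated = {
        s: evaluate_markers_in_sample(variants, marker_pool, s) for s in samples
    }
    rows = []
    n_undefined = 0
    for sa, sb in itertools.combinations(samples, 2):
        a, b = evaluated[sa], evaluated[sb]
        shared = len(a & b)
        total = len(a | b) if denominator == "union" else len(a) + len(b)
        pct = 100.0 * shared / total if total else None
        if pct is None:
            n_undefined += 1
        rows.append(
            {"sample_a": sa, "sample_b": sb, "shared": shared, "total": total,
             "percent_shared": pct}
        )
    if n_undefined:
        logger.info("%d pair(s) with empty marker union excluded as undefined", n_undefined)
    return pd.DataFrame(
        rows, columns=["sample_a", "sample_b", "shared", "total", "percent_shared"]
    )


def write_sharing(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")
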