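"""Hypergeometric over-representation of gene sets with BH-FDR control.

For a selected gene list drawn from a background universe, each gene set is
tested for over-representation with the upper tail of the hypergeometric
law: p = P(X >= n_overlap) where X ~ Hypergeom(|background|,
set_size_in_background, n_selected). p-values are corrected across all
tested sets with the Benjamini-Hochberg step-up procedure; a set is called
enriched when its q-value is at or below ``fdr_cutoff``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentRow:
    set_id: str
    description: str
    set_size_in_background: int
    n_selected: int
    n_overlap: int
    p_value: float
    q_value: float
    enriched: bool


@dataclass
class EnrichmentResult:
    rows: list[EnrichmentRow] = field(default_factory=list)
    n_background: int = 0
    n_skipped_small: int = 0
    fdr_cutoff: float = 0.01

    def to_frame(self) -> pd.DataFrame:
        cols = [
            "set_id",
            "description",
            "set_size_in_background",
            "n_selected",
            "n_overlap",
            "p_value",
            "q_value",
            "enriched",
        ]
        if not self.rows:
            return pd.DataFrame(columns=cols)
        df = pd.DataFrame([vars(r) for r in self.rows], columns=cols)
        df["enriched"] = df["enriched"].astype(int)
        return df

    @property
    def enriched_ids(self) -> list[str]:
        return [r.set_id for r in self.rows if r.enriched]


def hypergeometric_enrichment(
    selected: list[str],
    background: list[str],
    sets: GeneSetCollection,
    fdr_cutoff: float = 0.01,
    min_set_size: int = 3,
) -> EnrichmentResult:
    """Test every gene set for over-representation among ``selected``.

    ``background`` is the gene universe the selection was made from (for the
    compromise analysis: all genes that survived filtering). Sets are
    intersected with the background first; sets smaller than
    ``min_set_size`` afterwards are skipped (logged). Rows are ordered by
    (q, p, set_id) for deterministic output.
    """
    bg = set(background)
    if not bg:
        raise ValueError("background universe is empty")
    sel = set(selected)
    if not sel <= bg:
        extra = sorted(sel - bg)
        raise ValueError(f"selected genes not in background: {extra[:5]}")
    n_bg = len(bg)
    n_sel = len(sel)

    tested: list[tuple[str, str, int, int]] = []
    n_skipped = 0
    for sid in sorted(sets.sets):
        s = sets.sets[sid]
        members = [g for g in s.members if g in bg]
        if len(members) < min_set_size:
            n_skipped += 1
            continue
        overlap = sum(1 for g in members if g in sel)
        tested.append((sid, s.description, len(members), overlap))
    if n_skipped:
        logger.info(
            "enrichment: skipped %d sets with < %d members in background",
            n_skipped,
            min_set_size,
        )
    result = EnrichmentResult(
        n_background=n_bg, n_skipped_small=n_skipped, fdr_cutoff=fdr_cutoff
    )
    if not tested:
        return result

    pvals = [
        float(stats.hypergeom.sf(overlap - 1, n_bg, size, n_sel))
        for _, _, size, overlap in tested
    ]
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    rows = [
        EnrichmentRow(
            set_id=sid,
            description=desc,
            set_size_in_background=size,
            n_selected=n_sel,
            n_overlap=overlap,
            p_value=p,
            q_value=float(q),
            enriched=bool(q <= fdr_cutoff),
        )
        for (sid, desc, size, overlap), p, q in zip(tested, pvals, qvals)
    ]
    rows.sort(key=lambda r: (r.q_value, r.p_value, r.set_id))
    result.rows = rows
    return result
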