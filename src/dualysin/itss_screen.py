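"""The four-step filter cascade over per-gene top internal start candidates.

For each gene, the internal start candidate with the highest TIR is selected
and passed through four independent filters:

1. *outlier* -- the candidate's TIR must be clearly above the background of
   the gene's own internal candidates.  The default rule is the Tukey upper
   fence (TIR > Q3 + 1.5*IQR over all scored candidates of the gene); a
   z-score alternative is provided because the exact statistical rule for
   "clearly above background" is a modelling choice.  Note a single-candidate
   gene can never pass the Tukey rule: it is its own background.
2. *edge* -- the start must not fall within the first or last 20 codons
   (misannotated gene starts; products too small to fold a domain).
3. *domain* -- the start must not fall inside a conserved-domain interval
   (inclusive endpoints), which would generate a partial domain.
4. *tail* -- the protein must carry no phage tail domains, which flag
   misannotated virion-associated lysins.

A gene is retained iff it has a candidate and all four flags pass.  The
flags are computed independently, so retention status is a pure conjunction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .sequence_io import DomainHit, GeneRecord
from .tir_model import StartCandidate

logger = logging.getLogger(__name__)

#: Default phage-tail accession list (tail component / baseplate / minor tail).
DEFAULT_TAIL_ACCESSIONS = frozenset({"PF05709", "PF04865", "PF10145"})

FILTER_NAMES = ("outlier", "edge", "domain", "tail")


@dataclass
class FilterConfig:
    """Parameters of the 4-step cascade."""

    edge_window_aa: int = 20
    outlier_rule: str = "tukey"       # "tukey" or "zscore"
    tukey_fence: float = 1.5
    zscore_threshold: float = 2.0
    tail_accessions: frozenset[str] = DEFAULT_TAIL_ACCESSIONS

    def __post_init__(self) -> None:
        if self.edge_window_aa < 1:
            raise ValueError("edge_window_aa must be >= 1")
        if self.outlier_rule not in ("tukey", "zscore"):
            raise ValueError(f"unknown outlier rule {self.outlier_rule!r}")


@dataclass
class FilterFlags:
    outlier_pass: bool = False
    edge_pass: bool = False
    domain_pass: bool = False
    tail_pass: bool = False

    def all_pass(self) -> bool:
        return (
            self.outlier_pass and self.edge_pass and self.domain_pass and self.tail_pass
        )

    def failed(self) -> list[str]:
        return [
            name
            for name, ok in zip(
                FILTER_NAMES,
                (self.outlier_pass, self.edge_pass, self.domain_pass, self.tail_pass),
            )
            if not ok
        ]


@dataclass
class ITSSCall:
    """Per-gene screening outcome: the selected candidate plus the filter trace."""

    gene_id: str
    candidate: StartCandidate | None
    filters: FilterFlags
    status: str  # "retained" | "excluded" | "no_candidate"


@dataclass
class ScreenResult:
    calls: dict[str, ITSSCall]
    ranked: list[str]  # retained gene_ids by descending TIR (ties: gene_id)
    n_total: int = 0
    n_with_candidate: int = 0
    n_retained: int = 0
    fraction_retained: float = 0.0
    genes_without_domains: list[str] = field(default_factory=list)


@dataclass
class ComparisonReport:
    """Retained fractions of a target vs a control family and their ratio."""

    target_fraction: float | None
    control_fraction: float | None
    ratio: float | None


def select_top_candidate(
    scored: Sequence[StartCandidate],
) -> StartCandidate | None:
    """The maximum-TIR candidate of one gene; ties break to the smallest codon."""
    if not scored:
        return None
    gene_ids = {c.gene_id for c in scored}
    if len(gene_ids) > 1:
        raise ValueError(f"candidates from multiple genes: {sorted(gene_ids)}")
    return max(scored, key=lambda c: (c.tir, -c.codon_index))


def filter_outlier(
    candidate: StartCandidate,
    all_scored: Sequence[StartCandidate],
    cfg: FilterConfig,
) -> bool:
    """True iff the candidate's TIR is clearly above the gene's own background."""
    tirs = np.asarray([c.tir for c in all_scored], dtype=float)
    if cfg.outlier_rule == "tukey":
        q1, q3 = np.percentile(tirs, [25.0, 75.0])
        fence = q3 + cfg.tukey_fence * (q3 - q1)
        return bool(candidate.tir > fence)
    mean, sd = float(tirs.mean()), float(tirs.std(ddof=0))
    if sd == 0.0:
        return False
    return bool((candidate.tir - mean) / sd > cfg.zscore_threshold)


def filter_edges(
    candidate: StartCandidate, protein_len: int, cfg: FilterConfig
) -> bool:
    """True iff the start lies outside the first/last ``edge_window_aa`` codons."""
    w = cfg.edge_window_aa
    if protein_len <= 2 * w:
        return False
    return w < candidate.codon_index <= protein_len - w


def filter_domain_overlap(
    candidate: StartCandidate, domains: Iterable[DomainHit]
) -> bool:
    """True iff the start codon is inside no conserved-domain interval."""
    i = candidate.codon_index
    return not any(d.start_aa <= i <= d.end_aa for d in domains)


def filter_tail_domains(domains: Iterable[DomainHit], cfg: FilterConfig) -> bool:
    """True iff no hit is a phage tail domain (by category or accession)."""
    return not any(
        d.category == "tail" or d.accession in cfg.tail_accessions for d in domains
    )


def evaluate_gene(
    gene: GeneRecord,
    scored: Sequence[StartCandidate],
    domains: Sequence[DomainHit],
    cfg: FilterConfig,
) -> ITSSCall:
    """Select the top candidate of one gene and run all four filters on it."""
    top = select_top_candidate(scored)
    if top is None:
        return ITSSCall(gene.gene_id, None, FilterFlags(), "no_candidate")
    flags = FilterFlags(
        outlier_pass=filter_outlier(top, scored, cfg),
        edge_pass=filter_edges(top, len(gene.protein), cfg),
        domain_pass=filter_domain_overlap(top, domains),
        tail_pass=filter_tail_domains(domains, cfg),
    )
    status = "retained" if flags.all_pass() else "excluded"
    return ITSSCall(gene.gene_id, top, flags, status)


def run_screen(
    cohort: Sequence[GeneRecord],
    domains: Mapping[str, Sequence[DomainHit]],
    scores: Mapping[str, Sequence[StartCandidate]],
    cfg: FilterConfig | None = None,
) -> ScreenResult:
    """Apply the cascade to a cohort and rank the retained genes by TIR.

    Genes lacking any domain annotation are treated as passing the domain
    and tail filters (there is nothing to overlap) but are flagged in the
    result so the caller can audit them.
    """
    cfg = cfg or FilterConfig()
    calls: dict[str, ITSSCall] = {}
    no_domains: list[str] = []
    for gene in cohort:
        gene_domains = domains.get(gene.gene_id, ())
        if not gene_domains:
            no_domains.append(gene.gene_id)
        calls[gene.gene_id] = evaluate_gene(
            gene, scores.get(gene.gene_id, ()), gene_domains, cfg
        )
    retained = [c for c in calls.values() if c.status == "retained"]
    ranked = [
        c.gene_id
        for c in sorted(retained, key=lambda c: (-c.candidate.tir, c.gene_id))
    ]
    n_total = len(cohort)
    n_with = sum(1 for c in calls.values() if c.candidate is not None)
    n_ret = len(retained)
    if no_domains:
        logger.info(
            "%d gene(s) had no domain annotations; domain/tail filters passed "
            "vacuously", len(no_domains)
        )
    return ScreenResult(
        calls=calls,
        ranked=ranked,
        n_total=n_total,
        n_with_candidate=n_with,
        n_retained=n_ret,
        fraction_retained=(n_ret / n_total) if n_total else 0.0,
        genes_without_domains=no_domains,
    )


def compare_families(target: ScreenResult, control: ScreenResult) -> ComparisonReport:
    """Retained fractions of target vs control and their ratio (no test statistic)."""
    tf = target.fraction_retained if target.n_total else None
    cf = control.fraction_retained if control.n_total else None
    if tf is None or cf is None or cf == 0.0:
        ratio = None
    else:
        ratio = tf / cf
    return ComparisonReport(target_fraction=tf, control_fraction=cf, ratio=ratio)


def write_screen_tsv(result: ScreenResult, path) -> None:
    """Write per-gene calls: one row per gene with candidate, flags and status."""
    import pandas as pd

    rows = []
    for gid in sorted(result.calls):
        c = result.calls[gid]
        cand = c.candidate
        rows.append(
            {
                "gene_id": gid,
                "codon_index": cand.codon_index if cand else "",
                "start_codon": cand.start_codon if cand else "",
                "tir": cand.tir if cand else "",
                "outlier_pass": c.filters.outlier_pass,
                "edge_pass": c.filters.edge_pass,
                "domain_pass": c.filters.domain_pass,
                "tail_pass": c.filters.tail_pass,
                "status": c.status,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
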