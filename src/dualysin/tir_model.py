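"""Enumeration and scoring of in-frame internal translation start sites.

A gene with an internal, in-frame start codon (ATG/GTG/TTG) preceded by a
ribosome binding site can express a second, C-terminally nested protein from
the same reading frame.  This module enumerates every such candidate codon
and assigns each a translation initiation rate (TIR) in relative units.

Two scoring routes are supported and downstream stages are agnostic to
which is used:

* a precomputed :class:`~dualysin.sequence_io.TirTable`, so output of a
  full thermodynamic RBS-strength predictor can drive the pipeline; or
* the built-in simplified free-energy scorer implemented here.

The built-in scorer is deliberately minimal: it models only the
Shine-Dalgarno (SD) : anti-SD duplex using nearest-neighbor RNA stacking
energies, a spacing penalty, and a start-codon bonus, and maps the total
free energy to a rate through a Boltzmann-like relation

    TIR = k * exp(-beta * dG_total).

It makes no attempt to fold the mRNA or model standby sites, and its
absolute values are not comparable with published predictor outputs; ``k``
is calibrated so that a canonical AGGAGG site at optimal spacing scores
about 10,000 relative units, placing strong synthetic sites in the
empirically reported range for high-TIR internal starts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .sequence_io import GeneRecord, START_CODONS, TirTable

logger = logging.getLogger(__name__)

#: Nearest-neighbor stacking free energies for Watson-Crick RNA duplexes,
#: kcal/mol at 37 C (Turner-style parameters).  Keyed by the 5'->3'
#: dinucleotide of one strand; the two representations of each stack carry
#: the same value.
RNA_STACK_DG: dict[str, float] = {
    "AA": -0.93, "UU": -0.93,
    "AU": -1.10,
    "UA": -1.33,
    "CU": -2.08, "AG": -2.08,
    "CA": -2.11, "UG": -2.11,
    "GU": -2.24, "AC": -2.24,
    "GA": -2.35, "UC": -2.35,
    "CG": -2.36,
    "GG": -3.26, "CC": -3.26,
    "GC": -3.42,
}

DUPLEX_INIT_DG = 4.09   # helix initiation, kcal/mol
AU_END_DG = 0.45        # terminal A-U pair penalty, kcal/mol
CALIBRATION_TIR = 10_000.0
CALIBRATION_SPACING = 7

_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class StartCandidate:
    """An in-frame internal start codon, optionally with its TIR score."""

    gene_id: str
    codon_index: int          # 1-based codon index on the protein coordinate system
    start_codon: str          # ATG / GTG / TTG
    tir: float | None = None  # relative units; None while unscored
    sd_energy: float = 0.0    # SD:anti-SD duplex dG, kcal/mol (0 = no duplex)
    spacing_nt: int = 0       # aligned SD-start spacing, nt (0 = no duplex)


@dataclass
class AntiSD:
    """Parameters of the simplified SD-strength model for one host genus.

    ``anti_sd`` is the 16S rRNA anti-SD core the mRNA must pair with;
    ``beta`` converts free energy (kcal/mol) into log-rate; ``k`` is the
    rate scale and is calibrated on construction when left as None.
    ``window`` bounds the admissible SD-start spacing (nt between the last
    paired base and the start codon); spacings inside ``optimal_spacing``
    incur no penalty, outside it a quadratic penalty of
    ``spacing_coeff * offset**2`` kcal/mol applies.  Duplexes shorter than
    ``min_duplex`` consecutive pairs are treated as nonbinding.
    """

    genus: str = "default"
    anti_sd: str = "CCUCCU"
    beta: float = 0.45
    k: float | None = None
    window: tuple[int, int] = (4, 16)
    optimal_spacing: tuple[int, int] = (5, 10)
    spacing_coeff: float = 0.25
    min_duplex: int = 4
    start_bonus: Mapping[str, float] = field(
        default_factory=lambda: {"ATG": 0.0, "GTG": 1.0, "TTG": 2.0}
    )

    def __post_init__(self) -> None:
        if len(self.anti_sd) < 4:
            raise ValueError("anti-SD core must be at least 4 nt")
        if self.k is None:
            self.k = _calibrate_k(self)

    @property
    def sd_target(self) -> str:
        """The mRNA-side SD consensus (DNA alphabet): revcomp of the anti-SD."""
        dna = self.anti_sd.replace("U", "T")
        return dna.translate(_DNA_COMPLEMENT)[::-1]


def duplex_dg(segment: str) -> float:
    """Free energy of a fully Watson-Crick paired duplex given one strand.

    *segment* is the mRNA side, 5'->3', DNA or RNA alphabet.  Includes helix
    initiation and terminal A-U penalties.
    """
    rna = segment.replace("T", "U")
    dg = DUPLEX_INIT_DG
    for i in range(len(rna) - 1):
        dg += RNA_STACK_DG[rna[i : i + 2]]
    for end in (rna[0], rna[-1]):
        if end in "AU":
            dg += AU_END_DG
    return dg


def _spacing_penalty(model: AntiSD, spacing: int) -> float:
    lo, hi = model.optimal_spacing
    if spacing < lo:
        return model.spacing_coeff * (lo - spacing) ** 2
    if spacing > hi:
        return model.spacing_coeff * (spacing - hi) ** 2
    return 0.0


def _best_sd_duplex(upstream: str, model: AntiSD) -> tuple[float, float, int]:
    """Best (lowest) dG_hyb + spacing penalty over all SD placements.

    *upstream* is the mRNA immediately 5' of the start codon (DNA alphabet);
    its last character sits 1 nt before the start codon.  Returns
    ``(dG_hyb + penalty, dG_hyb, spacing)``; ``(0, 0, 0)`` when no duplex of
    at least ``min_duplex`` consecutive pairs fits the spacing window.
    """
    target = model.sd_target
    n, m = len(upstream), len(target)
    w_lo, w_hi = model.window
    best = (0.0, 0.0, 0)
    for i in range(n):
        for j in range(m):
            if upstream[i] != target[j]:
                continue
            # only evaluate maximal runs from their left end
            if i > 0 and j > 0 and upstream[i - 1] == target[j - 1]:
                continue
            run = 0
            while i + run < n and j + run < m and upstream[i + run] == target[j + run]:
                run += 1
            if run < model.min_duplex:
                continue
            # trimming the 3' end trades stacks for spacing; scan all suffixes
            for trim in range(0, run - model.min_duplex + 1):
                length = run - trim
                spacing = n - (i + length)
                if not (w_lo <= spacing <= w_hi):
                    continue
                dg = duplex_dg(upstream[i : i + length])
                total = dg + _spacing_penalty(model, spacing)
                if total < best[0]:
                    best = (total, dg, spacing)
    return best


def _calibrate_k(model: AntiSD) -> float:
    """Solve k so the canonical full SD at optimal spacing scores CALIBRATION_TIR."""
    dg = duplex_dg(model.sd_target)
    dg_total = dg + _spacing_penalty(model, CALIBRATION_SPACING)
    return CALIBRATION_TIR * math.exp(model.beta * dg_total)


def find_inframe_starts(gene: GeneRecord) -> list[StartCandidate]:
    """All internal in-frame ATG/GTG/TTG codons of a gene, unscored.

    Codon index 1 (the annotated start) and the stop codon are excluded;
    candidates are returned in ascending codon order.
    """
    cds = gene.cds.upper()
    out: list[StartCandidate] = []
    n_codons = len(cds) // 3 - 1  # exclude the stop codon
    for i in range(2, n_codons + 1):
        codon = cds[3 * (i - 1) : 3 * i]
        if codon in START_CODONS:
            out.append(StartCandidate(gene.gene_id, i, codon))
    return out


def score_tir(gene: GeneRecord, codon_index: int, model: AntiSD) -> StartCandidate:
    """Score one internal start candidate with the built-in model."""
    cds = gene.cds.upper()
    n_codons = len(cds) // 3 - 1
    if not (2 <= codon_index <= n_codons):
        raise ValueError(
            f"{gene.gene_id}: codon index {codon_index} is not a valid internal "
            f"start position (2..{n_codons})"
        )
    codon = cds[3 * (codon_index - 1) : 3 * codon_index]
    if codon not in START_CODONS:
        raise ValueError(
            f"{gene.gene_id}: codon {codon_index} is {codon}, not a start codon"
        )
    s0 = 3 * (codon_index - 1)
    max_reach = model.window[1] + len(model.anti_sd)
    upstream = cds[max(0, s0 - max_reach) : s0]
    dg_with_penalty, dg_hyb, spacing = _best_sd_duplex(upstream, model)
    dg_total = dg_with_penalty + model.start_bonus[codon]
    tir = model.k * math.exp(-model.beta * dg_total)
    return StartCandidate(
        gene_id=gene.gene_id,
        codon_index=codon_index,
        start_codon=codon,
        tir=tir,
        sd_energy=dg_hyb,
        spacing_nt=spacing,
    )


def score_gene(
    gene: GeneRecord,
    model_or_table: AntiSD | TirTable,
) -> list[StartCandidate]:
    """Score every internal start candidate of a gene.

    With a :class:`TirTable`, table values take precedence and the built-in
    model is never consulted; candidates absent from the table are excluded.
    A gene entirely absent from a supplied table is logged and returns an
    empty (unscored) list.
    """
    candidates = find_inframe_starts(gene)
    if isinstance(model_or_table, TirTable):
        table = model_or_table
        if candidates and gene.gene_id not in table.genes:
            logger.warning(
                "gene %s absent from the supplied TIR table; left unscored",
                gene.gene_id,
            )
            return []
        scored = []
        for c in candidates:
            tir = table.get(gene.gene_id, c.codon_index)
            if tir is not None:
                scored.append(replace(c, tir=tir))
        return scored
    return [score_tir(gene, c.codon_index, model_or_table) for c in candidates]


def score_cohort(
    records: Sequence[GeneRecord],
    model_or_table: AntiSD | TirTable | Mapping[str, AntiSD],
) -> dict[str, list[StartCandidate]]:
    """Score a whole cohort; accepts a per-genus model map with fallback.

    When a mapping of genus -> :class:`AntiSD` is given, each gene is scored
    with its host genus' parameters, falling back to the ``"default"`` entry
    (or a freshly built default model) for genera not in the map.
    """
    if isinstance(model_or_table, TirTable) or isinstance(model_or_table, AntiSD):
        return {r.gene_id: score_gene(r, model_or_table) for r in records}
    models = dict(model_or_table)
    fallback = models.get("default", AntiSD())
    return {
        r.gene_id: score_gene(r, models.get(r.host_genus, fallback)) for r in records
    }


def load_anti_sd_config(path: str) -> dict[str, AntiSD]:
    """Load per-genus anti-SD parameters from a JSON config.

    The JSON maps genus names to objects with any subset of the
    :class:`AntiSD` fields; omitted fields take the defaults.
    """
    import json

    with open(path) as fh:
        raw = json.load(fh)
    out = {}
    for genus, params in raw.items():
        params = dict(params)
        params.setdefault("genus", genus)
        if "window" in params:
            params["window"] = tuple(params["window"])
        if "optimal_spacing" in params:
            params["optimal_spacing"] = tuple(params["optimal_spacing"])
        out[genus] = AntiSD(**params)
    return out
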