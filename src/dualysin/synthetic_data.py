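"""Ground-truth synthetic cohorts for exercising the whole pipeline.

The generator emits gene cohorts shaped like a phage lytic-enzyme database
extract: coding + protein sequences, host-genus labels, conserved-domain
annotations with real Pfam accessions in the two recurring endolysin
architectures (two catalytic domains flanking the internal start, or one
catalytic domain with the start between it and the cell-wall binding
domain), and a negative-control family (portal-like proteins) with no
planted internal starts.

Construction is engineered so that truth recovery is a sharp test:

* backbone codons are drawn uniformly from sense codons *excluding* GTG and
  TTG, so every background internal start candidate is an ATG and, with no
  SD context, scores exactly the same baseline TIR -- a degenerate
  background on which the within-gene outlier rule can never fire by
  chance;
* Shine-Dalgarno-like motifs (every >= 4 nt run complementary to the
  anti-SD core) are rejected from the backbone outside the planted site,
  so only planted sites carry SD strength;
* background ATGs are confined to "safe" positions (outside the terminal
  edge windows and outside domain intervals) and at least five are
  guaranteed per gene, so single-gene background statistics are always
  defined and a weakly planted start fails only the outlier filter;
* each gene's intended filter outcome (retain, or fail exactly one of the
  four filters) is realized by construction, and the generator verifies
  every gene against the actual scorer + filter cascade at generation time,
  logging any collision (e.g. a planted site shadowed by a chance motif).

Everything is deterministic given the seed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import itss_screen, tir_model
from .sequence_io import (
    DomainHit,
    GeneRecord,
    START_CODONS,
    STOP_CODONS,
    translate_cds,
    validate_gene,
    write_cohort,
    write_domains,
)

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_ALL_CODONS = ["".join(c) for c in itertools.product(_BASES, repeat=3)]
#: Backbone sense codons: no stops, and no GTG/TTG so background internal
#: starts are all-ATG (see module docstring).
BACKBONE_CODONS = [
    c for c in _ALL_CODONS if c not in STOP_CODONS and c not in ("GTG", "TTG")
]
BACKBONE_NONSTART = [c for c in BACKBONE_CODONS if c != "ATG"]

#: 4-mer submotifs of the SD consensus AGGAGG; any complementary run of
#: >= 4 nt to the default anti-SD core contains one of these.
SD_SUBMOTIFS = ("AGGA", "GGAG", "GAGG")
SD_MOTIF = "AGGAGG"

DEFAULT_GENERA = (
    "Staphylococcus",
    "Streptococcus",
    "Lactococcus",
    "Enterococcus",
    "Clostridium",
    "Mycobacterium",
)

CATALYTIC_POOL = (
    ("PF01510", "Amidase_2"),
    ("PF05257", "CHAP"),
    ("PF01183", "Glyco_hydro_25"),
    ("PF01520", "Amidase_3"),
    ("PF01551", "Peptidase_M23"),
    ("PF01832", "Glucosaminidase"),
)
CWBD_POOL = (("PF08460", "SH3_5"), ("PF01473", "CW_binding_1"))
TAIL_POOL = (("PF05709", "Sipho_tail"), ("PF04865", "Baseplate_J"))
PORTAL = ("PF04860", "Phage_portal")

OUTCOMES = ("retain", "fail_outlier", "fail_edge", "fail_domain", "fail_tail")


@dataclass
class GeneratorConfig:
    """Study conditions of a synthetic cohort."""

    n_genes: int = 500
    itss_fraction: float = 0.5
    genus_weights: dict[str, float] | None = None
    architecture_mix: dict[str, float] = field(
        default_factory=lambda: {"group1": 0.35, "group2": 0.5, "none": 0.15}
    )
    planted_strength: str = "strong"  # strong | weak | mixed
    edge_violation_rate: float = 0.0
    domain_violation_rate: float = 0.0
    tail_rate: float = 0.0
    family: str = "endolysin"         # endolysin | control
    tag: str = ""
    seed: int = 0
    min_len: int = 230
    max_len: int = 320

    def __post_init__(self) -> None:
        if not (0.0 <= self.itss_fraction <= 1.0):
            raise ValueError("itss_fraction must be in [0, 1]")
        for rate in (self.edge_violation_rate, self.domain_violation_rate, self.tail_rate):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("violation rates must be in [0, 1]")
        if self.edge_violation_rate + self.domain_violation_rate + self.tail_rate > 1.0:
            raise ValueError("violation rates must sum to at most 1")
        if self.planted_strength not in ("strong", "weak", "mixed"):
            raise ValueError(f"unknown planted_strength {self.planted_strength!r}")
        mix_total = sum(self.architecture_mix.get(k, 0.0) for k in ("group1", "group2", "none"))
        if mix_total <= 0 and self.itss_fraction > 0:
            raise ValueError("architecture mix weights are all zero but planting is requested")
        if self.genus_weights is not None and sum(self.genus_weights.values()) <= 0:
            raise ValueError("genus weights must have positive total")


@dataclass
class TruthRecord:
    """Per-gene ground truth plus the generation-time verification outcome."""

    gene_id: str
    has_itss: bool
    itss_codon: int | None
    planted_class: str | None          # strong | weak | None
    intended_outcome: str              # retain | fail_* | none
    realized_status: str = ""
    realized_failed: tuple[str, ...] = ()
    realized_top_codon: int | None = None
    collision: bool = False


@dataclass
class SyntheticCohort:
    records: list[GeneRecord]
    domains: dict[str, list[DomainHit]]
    truth: list[TruthRecord]

    @property
    def collisions(self) -> list[str]:
        return [t.gene_id for t in self.truth if t.collision]


def _weighted_choice(rng: np.random.Generator, items: Sequence[str], weights) -> str:
    w = np.asarray([max(float(x), 0.0) for x in weights], dtype=float)
    w = w / w.sum()
    return str(items[int(rng.choice(len(items), p=w))])


def _draw_outcome(cfg: GeneratorConfig, rng: np.random.Generator) -> tuple[str, str]:
    """(strength, intended outcome) for one planted gene."""
    if cfg.planted_strength == "mixed":
        strength = "strong" if rng.random() < 0.5 else "weak"
    else:
        strength = cfg.planted_strength
    if strength == "weak":
        return strength, "fail_outlier"
    u = rng.random()
    if u < cfg.tail_rate:
        return strength, "fail_tail"
    if u < cfg.tail_rate + cfg.edge_violation_rate:
        return strength, "fail_edge"
    if u < cfg.tail_rate + cfg.edge_violation_rate + cfg.domain_violation_rate:
        return strength, "fail_domain"
    return strength, "retain"


def _layout(
    rng: np.random.Generator, L: int, arch: str, family: str, want_tail: bool
) -> tuple[list[DomainHit], dict[str, tuple[int, int]]]:
    """Domain intervals and the planting zones consistent with them."""

    def hit(acc_name: tuple[str, str], start: int, end: int, category: str) -> DomainHit:
        evalue = float(10.0 ** rng.uniform(-30, -5))
        return DomainHit(acc_name[0], acc_name[1], start, end, evalue, category)

    hits: list[DomainHit] = []
    zones: dict[str, tuple[int, int]] = {}
    if family == "control":
        hits.append(hit(PORTAL, 20, L - 30, "other"))
        return hits, zones

    if arch == "group2":
        cd_len = int(rng.integers(80, 121))
        cd = (25, 24 + cd_len)
        cwbd = (L - 70, L - 16)
        hits.append(hit(CATALYTIC_POOL[rng.integers(len(CATALYTIC_POOL))], *cd, "catalytic"))
        hits.append(hit(CWBD_POOL[rng.integers(len(CWBD_POOL))], *cwbd, "cwbd"))
        zones["retain"] = (cd[1] + 4, L - 76)
        zones["domain"] = (cd[0] + 5, cd[1] - 5)
        tail_span = cwbd
    elif arch == "group1":
        while True:
            le1 = int(rng.integers(50, 71))
            gap = int(rng.integers(28, 45))
            le2 = int(rng.integers(50, 71))
            if 24 + le1 + gap + le2 <= L - 60:
                break
        cd1 = (25, 24 + le1)
        cd2 = (cd1[1] + gap + 1, cd1[1] + gap + le2)
        cwbd = (L - 55, L - 16)
        pool = list(CATALYTIC_POOL)
        i1 = int(rng.integers(len(pool)))
        i2 = int(rng.integers(len(pool)))
        hits.append(hit(pool[i1], *cd1, "catalytic"))
        hits.append(hit(pool[i2], *cd2, "catalytic"))
        hits.append(hit(CWBD_POOL[rng.integers(len(CWBD_POOL))], *cwbd, "cwbd"))
        zones["retain"] = (cd1[1] + 4, cd2[0] - 4)
        zones["domain"] = (cd2[0] + 5, cd2[1] - 5)
        tail_span = cwbd
    else:  # no annotated domains
        zones["retain"] = (30, L - 85) if want_tail else (30, L - 30)
        tail_span = (L - 80, L - 35)

    if want_tail:
        hits.append(hit(TAIL_POOL[rng.integers(len(TAIL_POOL))], *tail_span, "tail"))
    zones["edge_early"] = (7, 20)
    zones["edge_late"] = (L - 15, L)
    hits.sort(key=lambda h: (h.start_aa, h.end_aa))
    return hits, zones


def _pick_in_zone(rng: np.random.Generator, zone: tuple[int, int]) -> int:
    lo, hi = zone
    if hi < lo:
        raise ValueError(f"empty planting zone {zone}")
    return int(rng.integers(lo, hi + 1))


class _GeneBuilder:
    """Mutable codon-level view of one gene under construction."""

    def __init__(self, rng: np.random.Generator, L: int):
        self.rng = rng
        self.L = L
        codons = ["ATG"] + [
            str(c) for c in rng.choice(BACKBONE_CODONS, size=L - 1)
        ]
        self.seq = list("".join(codons))
        self.protected: set[int] = {0}  # codon indices (0-based) never resampled

    def codon(self, c1: int) -> str:
        """Codon at 1-based index c1."""
        i = 3 * (c1 - 1)
        return "".join(self.seq[i : i + 3])

    def set_codon(self, c1: int, value: str) -> None:
        i = 3 * (c1 - 1)
        self.seq[i : i + 3] = list(value)

    def resample_codon(self, c1: int) -> None:
        self.set_codon(c1, str(self.rng.choice(BACKBONE_NONSTART)))

    # -- planting ----------------------------------------------------------

    def plant(self, itss: int, strong: bool, spacing: int) -> None:
        s0 = 3 * (itss - 1)
        self.set_codon(itss, "ATG")
        self.protected.add(itss - 1)
        if strong:
            ms = s0 - spacing - len(SD_MOTIF)
            if ms < 0:
                raise ValueError("planted start too close to the 5' end for its SD")
            self.seq[ms : ms + len(SD_MOTIF)] = list(SD_MOTIF)
            motif_codons = set(range(ms // 3, (ms + len(SD_MOTIF) - 1) // 3 + 1))
            self.protected |= motif_codons
            self._fix_boundary_codons(ms, ms + len(SD_MOTIF), itss)

    def _fix_boundary_codons(self, ms: int, me: int, itss: int) -> None:
        """Codons partially overwritten by the SD motif must stay sense,
        non-start codons; only their backbone-owned characters may change."""
        bad = STOP_CODONS | set(START_CODONS)
        for c0 in range(ms // 3, (me - 1) // 3 + 1):
            if c0 + 1 == itss:
                continue
            free = [p for p in range(3 * c0, 3 * c0 + 3) if not (ms <= p < me)]
            guard = 0
            while self.codon(c0 + 1) in bad and free and guard < 50:
                p = free[int(self.rng.integers(len(free)))]
                self.seq[p] = str(self.rng.choice(list("AC")))
                guard += 1

    # -- background start management --------------------------------------

    def _safe(self, c1: int, hits: list[DomainHit], itss: int | None) -> bool:
        if not (20 < c1 <= self.L - 20):
            return False
        if any(h.start_aa <= c1 <= h.end_aa for h in hits):
            return False
        if itss is not None and abs(c1 - itss) <= 4:
            return False
        return True

    def clear_unsafe_starts(self, hits: list[DomainHit], itss: int | None) -> bool:
        changed = False
        for c1 in range(2, self.L + 1):
            if c1 == itss or (c1 - 1) in self.protected:
                continue
            if self.codon(c1) in START_CODONS and not self._safe(c1, hits, itss):
                self.resample_codon(c1)
                changed = True
        return changed

    def enforce_min_atg(
        self, hits: list[DomainHit], itss: int | None, minimum: int = 5
    ) -> bool:
        safe_atg = [
            c1
            for c1 in range(2, self.L + 1)
            if c1 != itss and self.codon(c1) == "ATG" and self._safe(c1, hits, itss)
        ]
        if len(safe_atg) >= minimum:
            return False
        slots = [
            c1
            for c1 in range(2, self.L + 1)
            if c1 != itss
            and (c1 - 1) not in self.protected
            and self._safe(c1, hits, itss)
            and self.codon(c1) != "ATG"
        ]
        need = minimum - len(safe_atg)
        chosen = self.rng.choice(len(slots), size=need, replace=False)
        for idx in sorted(int(i) for i in chosen):
            self.set_codon(slots[idx], "ATG")
            self.protected.add(slots[idx] - 1)
        return True

    def reject_sd_motifs(self, max_rounds: int = 300) -> bool:
        """Remove SD-like runs (any AGGAGG 4-mer submotif) outside protection."""
        atg_codons = {
            c1 - 1 for c1 in range(1, self.L + 1) if self.codon(c1) == "ATG"
        }
        shielded = self.protected | atg_codons
        changed = False
        skipped: set[int] = set()
        for _ in range(max_rounds):
            s = "".join(self.seq)
            target = None
            for motif in SD_SUBMOTIFS:
                start = s.find(motif)
                while start != -1:
                    codons = set(range(start // 3, (start + len(motif) - 1) // 3 + 1))
                    if start not in skipped and not codons <= shielded:
                        if target is None or start < target[0]:
                            target = (start, codons)
                        break
                    start = s.find(motif, start + 1)
            if target is None:
                break
            start, codons = target
            open_codons = sorted(codons - shielded)
            if not open_codons:
                skipped.add(start)
                continue
            self.resample_codon(open_codons[0] + 1)
            changed = True
        return changed

    # -- output ------------------------------------------------------------

    def finish(self) -> str:
        return "".join(self.seq) + "TAA"


def generate_gene(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    gene_id: str,
    forced_has_itss: bool | None = None,
    forced_outcome: str | None = None,
) -> tuple[GeneRecord, list[DomainHit], TruthRecord]:
    """One gene with its domain hits and ground truth.

    ``forced_has_itss`` / ``forced_outcome`` override the configured random
    draws; this is how hand-built fixtures with known per-gene outcomes are
    assembled.
    """
    L = int(rng.integers(cfg.min_len, cfg.max_len + 1))
    genera = (
        sorted(cfg.genus_weights) if cfg.genus_weights else list(DEFAULT_GENERA)
    )
    weights = (
        [cfg.genus_weights[g] for g in genera]
        if cfg.genus_weights
        else [1.0] * len(genera)
    )
    genus = _weighted_choice(rng, genera, weights)

    if cfg.family == "control":
        has_itss = False
    elif forced_has_itss is not None:
        has_itss = forced_has_itss
    else:
        has_itss = bool(rng.random() < cfg.itss_fraction)

    strength: str | None = None
    intended = "none"
    if has_itss:
        if forced_outcome is not None:
            if forced_outcome not in OUTCOMES:
                raise ValueError(f"unknown outcome {forced_outcome!r}")
            intended = forced_outcome
            strength = "weak" if intended == "fail_outlier" else "strong"
        else:
            strength, intended = _draw_outcome(cfg, rng)

    arch_keys = ("group1", "group2", "none")
    arch = _weighted_choice(
        rng, arch_keys, [cfg.architecture_mix.get(k, 0.0) for k in arch_keys]
    )
    if intended == "fail_domain" and arch == "none":
        w1 = cfg.architecture_mix.get("group1", 0.0)
        w2 = cfg.architecture_mix.get("group2", 0.0)
        arch = (
            _weighted_choice(rng, ("group1", "group2"), (w1, w2))
            if (w1 + w2) > 0
            else "group2"
        )

    hits, zones = _layout(rng, L, arch, cfg.family, want_tail=(intended == "fail_tail"))

    itss: int | None = None
    if has_itss:
        if intended == "fail_edge":
            zone = zones["edge_early"] if rng.random() < 0.5 else zones["edge_late"]
        elif intended == "fail_domain":
            zone = zones["domain"]
        else:
            zone = zones["retain"]
        itss = _pick_in_zone(rng, zone)

    builder = _GeneBuilder(rng, L)
    if itss is not None:
        spacing = int(rng.integers(5, 8))
        builder.plant(itss, strong=(strength == "strong"), spacing=spacing)
    for _ in range(5):
        c1 = builder.clear_unsafe_starts(hits, itss)
        c2 = builder.enforce_min_atg(hits, itss)
        c3 = builder.reject_sd_motifs()
        if not (c1 or c2 or c3):
            break

    cds = builder.finish()
    record = GeneRecord(
        gene_id=gene_id,
        cds=cds,
        protein=translate_cds(cds),
        host_genus=genus,
        family=cfg.family,
        source="synthetic",
    )
    problems = validate_gene(record)
    if problems:  # pragma: no cover - generator invariant
        raise AssertionError(f"generator produced an invalid gene: {problems}")

    truth = TruthRecord(
        gene_id=gene_id,
        has_itss=has_itss,
        itss_codon=itss,
        planted_class=strength,
        intended_outcome=intended,
    )
    return record, hits, truth


def _verify(
    record: GeneRecord,
    hits: list[DomainHit],
    truth: TruthRecord,
    model: tir_model.AntiSD,
    fcfg: itss_screen.FilterConfig,
) -> None:
    """Run the actual scorer + cascade on one gene and record collisions."""
    scored = tir_model.score_gene(record, model)
    call = itss_screen.evaluate_gene(record, scored, hits, fcfg)
    truth.realized_status = call.status
    truth.realized_failed = tuple(call.filters.failed()) if call.candidate else ()
    truth.realized_top_codon = call.candidate.codon_index if call.candidate else None

    intended = truth.intended_outcome
    if not truth.has_itss:
        ok = call.status != "retained"
    elif intended == "retain":
        ok = (
            call.status == "retained"
            and truth.realized_top_codon == truth.itss_codon
        )
    elif intended == "fail_outlier":
        ok = call.status == "excluded" and truth.realized_failed == ("outlier",)
    else:
        name = intended.removeprefix("fail_")
        ok = (
            call.status == "excluded"
            and truth.realized_failed == (name,)
            and truth.realized_top_codon == truth.itss_codon
        )
    truth.collision = not ok
    if truth.collision:
        logger.info(
            "collision: %s intended %s, realized %s (failed %s, top codon %s)",
            truth.gene_id,
            intended,
            call.status,
            truth.realized_failed,
            truth.realized_top_codon,
        )


def generate_cohort(
    cfg: GeneratorConfig, outdir: str | Path | None = None
) -> SyntheticCohort:
    """A full cohort with truth, optionally written out as pipeline inputs.

    When *outdir* is given, the exact formats the readers consume are
    written: cds.fasta, proteins.fasta, metadata.tsv, domains.tsv and
    truth.tsv.
    """
    rng = np.random.default_rng(cfg.seed)
    model = tir_model.AntiSD()
    fcfg = itss_screen.FilterConfig()
    prefix = "ctrl" if cfg.family == "control" else "endo"

    records: list[GeneRecord] = []
    domains: dict[str, list[DomainHit]] = {}
    truths: list[TruthRecord] = []
    for i in range(cfg.n_genes):
        gid = f"{prefix}_{i:05d}"
        rec, hits, truth = generate_gene(cfg, rng, gid)
        _verify(rec, hits, truth, model, fcfg)
        records.append(rec)
        domains[gid] = hits
        truths.append(truth)

    cohort = SyntheticCohort(records=records, domains=domains, truth=truths)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_cohort(records, outdir)
        write_domains(domains, outdir / "domains.tsv")
        pd.DataFrame(
            {
                "gene_id": [t.gene_id for t in truths],
                "has_itss": [t.has_itss for t in truths],
                "itss_codon": [t.itss_codon if t.itss_codon else "" for t in truths],
                "planted_class": [t.planted_class or "" for t in truths],
                "intended_outcome": [t.intended_outcome for t in truths],
                "realized_status": [t.realized_status for t in truths],
                "realized_failed": [
                    ";".join(t.realized_failed) for t in truths
                ],
                "collision": [t.collision for t in truths],
            }
        ).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return cohort
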