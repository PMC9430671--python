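"""Identity clustering, iTSS positional consensus, products and architectures.

Protein sequences are clustered by percent identity: pairs above a threshold
form edges and single-linkage connected components form clusters, which is
the natural reading of "over X% identity" as a graph criterion.  Within each
cluster, the internal-start positions of the members are mapped onto a common
coordinate system to ask whether the predicted starts sit at the same
relative position -- recurrent, positionally conserved starts across
homologues are stronger evidence than isolated predictions.

The module also derives the two protein products implied by an internal
start -- the full-length product (FLP) and the C-terminal product (CTP, a
suffix of the FLP whose first residue is read as Met) -- and classifies the
domain architecture into the two recurring layouts:

* group 1: two catalytic domains with the internal start between them, so
  the CTP keeps the second catalytic domain plus the cell-wall binding
  domain (CWBD);
* group 2: a single catalytic domain upstream of the internal start, so the
  CTP carries only the CWBD moiety.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from Bio import Align

from . import massmetry
from .sequence_io import DomainHit, GeneRecord
from .itss_screen import ITSSCall


@dataclass
class Cluster:
    cluster_id: str
    members: list[str]
    threshold_pct: float
    representative: str


@dataclass
class ConsensusRecord:
    """Positional consensus of internal starts within one cluster."""

    consensus_column: int | None
    support_fraction: float
    columns: dict[str, int] = field(default_factory=dict)


@dataclass
class ProductPair:
    flp_seq: str
    ctp_seq: str
    flp_mass_da: float
    ctp_mass_da: float
    tag_seq: str = ""


@dataclass
class Architecture:
    gene_id: str
    flp_domains: list[DomainHit]
    ctp_domains: list[DomainHit]
    group: str  # "group1_two_CDs" | "group2_one_CD" | "unclassified"


def _make_aligner() -> Align.PairwiseAligner:
    # identity objective: maximize matches; small affine gap costs keep
    # alignments compact without rewarding spurious gapping
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -0.6
    aligner.extend_gap_score = -0.1
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: str, b: str, denominator: str = "alignment") -> float:
    """Percent identity of a global alignment of two protein sequences.

    With ``denominator="alignment"`` (default) identity is
    100 * matches / alignment length, counting every gap column; with
    ``denominator="shorter"`` the shorter sequence length is used instead.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    # canonical pair order: among co-optimal alignments the traceback choice
    # can depend on argument order, so fix it for exact symmetry
    if b < a:
        a, b = b, a
    aln = _ALIGNER.align(a, b)[0]
    counts = aln.counts()
    matches = counts.identities
    if denominator == "alignment":
        denom = counts.identities + counts.mismatches + counts.gaps
    elif denominator == "shorter":
        denom = min(len(a), len(b))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return 100.0 * matches / denom


def cluster_by_identity(
    seqs: Mapping[str, str],
    threshold_pct: float,
    denominator: str = "alignment",
) -> list[Cluster]:
    """Single-linkage clusters of the identity graph with edges > threshold.

    Deterministic and invariant to input order: members, representatives and
    cluster ids are all derived from sorted gene ids.  The representative of
    each cluster is its longest member (ties to the lexicographically
    smallest id).
    """
    if not (0.0 < threshold_pct <= 100.0):
        raise ValueError("threshold must be in (0, 100]")
    ids = sorted(seqs)
    parent = {g: g for g in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if pairwise_identity(seqs[a], seqs[b], denominator) > threshold_pct:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)

    groups: dict[str, list[str]] = {}
    for g in ids:
        groups.setdefault(find(g), []).append(g)
    clusters = []
    for idx, root in enumerate(sorted(groups)):
        members = sorted(groups[root])
        rep = max(members, key=lambda g: (len(seqs[g]), [-ord(c) for c in g]))
        clusters.append(
            Cluster(
                cluster_id=f"C{idx:04d}",
                members=members,
                threshold_pct=threshold_pct,
                representative=rep,
            )
        )
    return clusters


def _map_to_reference(ref: str, seq: str) -> dict[int, int]:
    """Map 1-based residue indices of *seq* to 1-based positions on *ref*.

    Residues inserted relative to the reference inherit the position of the
    last aligned reference residue, so nearby insertions land on nearby
    columns.
    """
    aln = _ALIGNER.align(ref, seq)[0]
    ref_row, seq_row = str(aln[0]), str(aln[1])
    mapping: dict[int, int] = {}
    ref_pos = seq_pos = 0
    for rc, sc in zip(ref_row, seq_row):
        if rc != "-":
            ref_pos += 1
        if sc != "-":
            seq_pos += 1
            mapping[seq_pos] = max(ref_pos, 1)
    return mapping


def itss_position_consensus(
    cluster: Cluster,
    calls: Mapping[str, ITSSCall],
    seqs: Mapping[str, str],
    msa: Mapping[str, str] | None = None,
    tolerance: int = 2,
) -> ConsensusRecord:
    """Do the cluster members' internal starts sit at the same relative position?

    Each member's start codon is mapped to a common coordinate: a column of a
    supplied multiple alignment (``msa``, gapped sequences), or, by default,
    the position on the cluster representative via pairwise (star) alignment.
    The consensus column is the modal mapped position provided more than half
    of the members with a call fall within ``tolerance`` columns of it.
    """
    columns: dict[str, int] = {}
    for gid in cluster.members:
        call = calls.get(gid)
        if call is None or call.candidate is None:
            continue
        codon = call.candidate.codon_index
        if msa is not None:
            if gid not in msa:
                raise ValueError(f"cluster member {gid} missing from the alignment")
            gapped = msa[gid]
            residue = 0
            col = None
            for ci, ch in enumerate(gapped, start=1):
                if ch != "-":
                    residue += 1
                    if residue == codon:
                        col = ci
                        break
            if col is None:
                raise ValueError(
                    f"{gid}: codon {codon} beyond aligned sequence length"
                )
            columns[gid] = col
        else:
            mapping = _map_to_reference(seqs[cluster.representative], seqs[gid])
            columns[gid] = mapping[codon]
    if not columns:
        return ConsensusRecord(None, 0.0, {})
    counts = Counter(columns.values())
    mode = min(counts, key=lambda c: (-counts[c], c))
    support = sum(1 for c in columns.values() if abs(c - mode) <= tolerance) / len(
        columns
    )
    consensus = mode if support > 0.5 else None
    return ConsensusRecord(consensus, support, columns)


def derive_products(
    gene: GeneRecord, itss_codon: int, tag: str = ""
) -> ProductPair:
    """The FLP/CTP product pair implied by an internal start.

    The CTP is the FLP suffix starting at the internal start codon with its
    first residue read as Met; an optional C-terminal tag (e.g. the
    hexahistidine tag PGGGSHHHHHH used for detection) is appended to both
    products and included in the average-mass calculations.
    """
    protein = gene.protein
    if not (2 <= itss_codon <= len(protein)):
        raise ValueError(
            f"{gene.gene_id}: internal start codon {itss_codon} outside 2..{len(protein)}"
        )
    flp = protein + tag
    ctp = "M" + protein[itss_codon:] + tag
    return ProductPair(
        flp_seq=flp,
        ctp_seq=ctp,
        flp_mass_da=massmetry.sequence_mass(flp, kind="average"),
        ctp_mass_da=massmetry.sequence_mass(ctp, kind="average"),
        tag_seq=tag,
    )


def classify_architecture(
    domains: Sequence[DomainHit], itss_codon: int, gene_id: str = ""
) -> Architecture:
    """Assign the two-group architecture taxonomy from domain layout and start.

    group1_two_CDs: at least two catalytic domains with the internal start
    strictly between two consecutive ones.  group2_one_CD: exactly one
    catalytic domain, entirely upstream of the internal start.  Everything
    else (no catalytic hit, start inside or upstream of the only catalytic
    domain, ...) is unclassified.
    """
    hits = sorted(domains, key=lambda h: (h.start_aa, h.end_aa))
    ctp_hits = [
        DomainHit(
            accession=h.accession,
            name=h.name,
            start_aa=h.start_aa - itss_codon + 1,
            end_aa=h.end_aa - itss_codon + 1,
            evalue=h.evalue,
            category=h.category,
        )
        for h in hits
        if h.start_aa >= itss_codon
    ]
    cats = [h for h in hits if h.category == "catalytic"]
    group = "unclassified"
    if len(cats) >= 2:
        for first, second in zip(cats, cats[1:]):
            if first.end_aa < itss_codon < second.start_aa:
                group = "group1_two_CDs"
                break
    elif len(cats) == 1 and cats[0].end_aa < itss_codon:
        group = "group2_one_CD"
    return Architecture(
        gene_id=gene_id, flp_domains=hits, ctp_domains=ctp_hits, group=group
    )


# ---------------------------------------------------------------------------
# tabular / FASTA outputs
# ---------------------------------------------------------------------------


def write_clusters_tsv(
    clusters: Sequence[Cluster],
    consensus: Mapping[str, ConsensusRecord],
    path: str | Path,
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("cluster_id\tmember\trepresentative\tconsensus_column\tsupport\n")
        for cl in clusters:
            cons = consensus.get(cl.cluster_id)
            col = cons.consensus_column if cons and cons.consensus_column else ""
            sup = f"{cons.support_fraction:.3f}" if cons else ""
            for m in cl.members:
                fh.write(f"{cl.cluster_id}\t{m}\t{cl.representative}\t{col}\t{sup}\n")
    return path


def write_architectures_tsv(
    architectures: Sequence[Architecture], path: str | Path
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("gene_id\tgroup\tflp_domains\tctp_domains\n")
        for a in architectures:
            flp = ";".join(f"{h.name}:{h.start_aa}-{h.end_aa}" for h in a.flp_domains)
            ctp = ";".join(f"{h.name}:{h.start_aa}-{h.end_aa}" for h in a.ctp_domains)
            fh.write(f"{a.gene_id}\t{a.group}\t{flp}\t{ctp}\n")
    return path


def write_products_fasta(
    products: Mapping[str, ProductPair], path: str | Path
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for gid in sorted(products):
            p = products[gid]
            fh.write(f">{gid}_FLP mass_da={p.flp_mass_da:.2f}\n{p.flp_seq}\n")
            fh.write(f">{gid}_CTP mass_da={p.ctp_mass_da:.2f}\n{p.ctp_seq}\n")
    return path
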