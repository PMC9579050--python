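"""Domain-architecture classification of receptor families.

Each primary-transcript protein is classified by presence/absence rules on
its Pfam domain hits and transmembrane-helix count:

* **LRR-RLK** — length >= 250 AA, a protein-kinase hit (PF00069, full-sequence
  E <= 1e-10) and at least one LRR hit (any of 14 LRR Pfam families,
  E <= 1e-2).
* **LRR-RLP** — length >= 150 AA, an LRR hit, *no* kinase hit passing the
  kinase threshold, a C3F juxtamembrane-domain hit (E <= 1e-10 with alignment
  length >= 140 residues) and at least one transmembrane helix.
* **NB-ARC** — length >= 150 AA and an NB-ARC hit (PF00931, E <= 1e-10).
* **LysM-RLK / LysM-RLP** — length >= 150 AA, a LysM hit (PF01476, permissive
  E <= 1000) and a transmembrane helix; split by kinase-domain presence.

LRR-RLK candidates are further assigned to one of the 20 canonical
subgroups by aligning the highest-scoring kinase-domain region against a
reference panel of subgroup-labelled kinase domains (Smith-Waterman local
alignment, BLOSUM62, gap open 11 / extend 1, best hit above a significance
floor).

All E-value thresholds apply to the full-sequence E-value and are inclusive
on the passing side; Pfam accessions are matched version-tolerantly
(``PF00069.26`` passes a ``PF00069`` rule).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from receptoire.io import DomainHit, ProteinRecord, TmRecord

logger = logging.getLogger(__name__)

__all__ = [
    "RuleThresholds",
    "ReceptorCall",
    "ReferenceKinasePanel",
    "LRR_RLK_SUBGROUPS",
    "FAMILIES",
    "classify_lrr_rlk",
    "classify_lrr_rlp",
    "classify_nbarc",
    "classify_lysm",
    "extract_kinase_region",
    "local_align_score",
    "assign_subgroup",
    "identify_repertoire",
    "ClassificationError",
]


class ClassificationError(ValueError):
    """Raised when a protein cannot be classified due to missing inputs."""


#: The 20 canonical LRR-RLK subgroups, defined by kinase-domain similarity.
LRR_RLK_SUBGROUPS = (
    "I", "II", "III", "IV", "V",
    "VI_1", "VI_2", "VII_1", "VII_2", "VII_3",
    "VIII_1", "VIII_2", "IX", "Xa", "Xb",
    "XI", "XII", "XIII", "XIV", "XV",
)

FAMILIES = ("LRR-RLK", "LRR-RLP", "LysM-RLK", "LysM-RLP", "NB-ARC")

#: LRR Pfam families accepted as evidence of an LRR ectodomain.
DEFAULT_LRR_ACCS = frozenset(
    {
        "PF18805", "PF18831", "PF18837", "PF00560", "PF07723", "PF07725",
        "PF12799", "PF13306", "PF13516", "PF13855", "PF14580", "PF01463",
        "PF08263", "PF01462",
    }
)


@dataclass(frozen=True)
class RuleThresholds:
    """All tunable cut-offs of the classification rules.

    E-value thresholds are inclusive (a hit at exactly the threshold passes);
    length floors are inclusive as well.
    """

    kinase_acc: str = "PF00069"
    kinase_evalue: float = 1e-10
    lrr_accs: frozenset = DEFAULT_LRR_ACCS
    lrr_evalue: float = 1e-2
    nbarc_acc: str = "PF00931"
    nbarc_evalue: float = 1e-10
    lysm_acc: str = "PF01476"
    lysm_evalue: float = 1000.0
    c3f_acc: str = "C3F"
    c3f_evalue: float = 1e-10
    c3f_min_ali_length: int = 140
    min_len_rlk: int = 250
    min_len_other: int = 150
    # significance floor for subgroup assignment (bit-score approximation of
    # the aligner's E <= 1e-10 cut-off; see docs/methods.md)
    subgroup_min_score: float = 50.0

    def __post_init__(self):
        for name in ("kinase_evalue", "lrr_evalue", "nbarc_evalue",
                     "lysm_evalue", "c3f_evalue"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.lrr_accs:
            raise ValueError("lrr_accs must be non-empty")


DEFAULT_THRESHOLDS = RuleThresholds()


@dataclass(frozen=True)
class ReceptorCall:
    """One (protein, family) classification, with subgroup for LRR-RLKs."""

    protein_id: str
    family: str
    subgroup: Optional[str] = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.subgroup is not None and self.family != "LRR-RLK":
            raise ValueError("subgroup is only meaningful for LRR-RLK calls")


@lru_cache(maxsize=64)
def _acc_base(acc: str) -> str:
    return acc.split(".", 1)[0]


def _acc_matches(hit: DomainHit, acc: str) -> bool:
    return hit.pfam_base == _acc_base(acc)


def _has_hit(hits: Iterable[DomainHit], acc: str, evalue: float) -> bool:
    return any(_acc_matches(h, acc) and h.seq_evalue <= evalue for h in hits)


@lru_cache(maxsize=8)
def _lrr_bases(accs: frozenset) -> frozenset:
    return frozenset(a.split(".", 1)[0] for a in accs)


def _has_lrr(hits: Iterable[DomainHit], t: RuleThresholds) -> bool:
    bases = _lrr_bases(t.lrr_accs)
    return any(h.pfam_base in bases and h.seq_evalue <= t.lrr_evalue for h in hits)


def classify_lrr_rlk(
    protein: ProteinRecord,
    hits: Sequence[DomainHit],
    t: RuleThresholds = DEFAULT_THRESHOLDS,
) -> bool:
    """LRR receptor-like kinase: >=250 AA with kinase and LRR domains."""
    return (
        protein.length >= t.min_len_rlk
        and _has_hit(hits, t.kinase_acc, t.kinase_evalue)
        and _has_lrr(hits, t)
    )


def classify_lrr_rlp(
    protein: ProteinRecord,
    hits: Sequence[DomainHit],
    tm: Optional[TmRecord],
    t: RuleThresholds = DEFAULT_THRESHOLDS,
) -> bool:
    """LRR receptor-like protein: LRR + C3F + TM helix, no kinase domain.

    Raises :class:`ClassificationError` if the protein satisfies every
    sequence-level requirement but has no transmembrane record — TM evidence
    is then required to decide the call, not optional.
    """
    if protein.length < t.min_len_other:
        return False
    if not _has_lrr(hits, t):
        return False
    if _has_hit(hits, t.kinase_acc, t.kinase_evalue):
        return False
    c3f_ok = any(
        _acc_matches(h, t.c3f_acc)
        and h.seq_evalue <= t.c3f_evalue
        and h.ali_length >= t.c3f_min_ali_length
        for h in hits
    )
    if not c3f_ok:
        return False
    if tm is None:
        raise ClassificationError(
            f"protein {protein.protein_id!r} is an LRR-RLP candidate but has "
            "no transmembrane record"
        )
    return tm.n_helices >= 1


def classify_nbarc(
    protein: ProteinRecord,
    hits: Sequence[DomainHit],
    t: RuleThresholds = DEFAULT_THRESHOLDS,
) -> bool:
    """NB-ARC intracellular receptor: >=150 AA with an NB-ARC domain."""
    return protein.length >= t.min_len_other and _has_hit(
        hits, t.nbarc_acc, t.nbarc_evalue
    )


def classify_lysm(
    protein: ProteinRecord,
    hits: Sequence[DomainHit],
    tm: Optional[TmRecord],
    t: RuleThresholds = DEFAULT_THRESHOLDS,
) -> Optional[str]:
    """LysM receptor: returns ``"LysM-RLK"``, ``"LysM-RLP"`` or ``None``.

    Requires a LysM domain (permissive E-value) plus a transmembrane helix;
    kinase-domain presence splits RLK from RLP.  A missing TM record counts
    as no helix (the permissive LysM search makes TM evidence the effective
    filter, so absence of evidence is treated as absence).
    """
    if protein.length < t.min_len_other:
        return None
    if not _has_hit(hits, t.lysm_acc, t.lysm_evalue):
        return None
    if tm is None or tm.n_helices == 0:
        return None
    if _has_hit(hits, t.kinase_acc, t.kinase_evalue):
        return "LysM-RLK"
    return "LysM-RLP"


def extract_kinase_region(
    protein: ProteinRecord,
    hits: Sequence[DomainHit],
    t: RuleThresholds = DEFAULT_THRESHOLDS,
) -> str:
    """Subsequence at the envelope of the highest-scoring kinase hit.

    Ties on bit score are broken by smallest envelope start.  Envelope
    coordinates are 1-based inclusive.
    """
    kinase_hits = [
        h
        for h in hits
        if _acc_matches(h, t.kinase_acc) and h.seq_evalue <= t.kinase_evalue
    ]
    if not kinase_hits:
        raise ClassificationError(
            f"protein {protein.protein_id!r} has no qualifying kinase hit"
        )
    best = max(kinase_hits, key=lambda h: (h.bitscore, -h.env_start))
    return protein.sequence[best.env_start - 1 : best.env_end]


_aligner = Align.PairwiseAligner(
    mode="local",
    substitution_matrix=substitution_matrices.load("BLOSUM62"),
    open_gap_score=-11.0,
    extend_gap_score=-1.0,
)


def local_align_score(query: str, target: str) -> float:
    """Smith-Waterman optimal local alignment score.

    BLOSUM62 with affine gaps (open 11, extend 1); symmetric in its
    arguments and floored at 0 (the empty local alignment).
    """
    if not query or not target:
        raise ValueError("sequences must be non-empty")
    return max(0.0, float(_aligner.score(query.upper(), target.upper())))


@dataclass
class ReferenceKinasePanel:
    """Subgroup-labelled reference kinase-domain sequences.

    ``entries`` is an ordered list of ``(subgroup_label, sequence)``.  When
    built from full-length reference receptors with their domain hits
    (:meth:`from_reference_proteins`), entries failing the LRR-RLK rule are
    pruned and their kinase regions extracted, mirroring how candidate
    proteins are processed.
    """

    entries: list = field(default_factory=list)

    def __post_init__(self):
        for label, seq in self.entries:
            if label not in LRR_RLK_SUBGROUPS:
                raise ValueError(f"unknown subgroup label {label!r}")
            if not seq:
                raise ValueError(f"empty panel sequence for subgroup {label!r}")

    @classmethod
    def from_reference_proteins(
        cls,
        proteins: Sequence[ProteinRecord],
        hits_by_protein: Mapping[str, Sequence[DomainHit]],
        subgroup_of: Mapping[str, str],
        t: RuleThresholds = DEFAULT_THRESHOLDS,
    ) -> "ReferenceKinasePanel":
        """Build a panel from full-length references, pruning by the filters.

        Reference receptors that fail the kinase/LRR/length rule are dropped
        (with a log message) rather than kept — the panel must pass the same
        thresholds it is used to classify against.
        """
        entries = []
        dropped = []
        for p in proteins:
            h = hits_by_protein.get(p.protein_id, ())
            if not classify_lrr_rlk(p, h, t):
                dropped.append(p.protein_id)
                continue
            entries.append((subgroup_of[p.protein_id], extract_kinase_region(p, h, t)))
        if dropped:
            logger.info(
                "panel pruning removed %d reference sequence(s): %s",
                len(dropped), dropped,
            )
        return cls(entries=entries)

    def __len__(self):
        return len(self.entries)


def assign_subgroup(
    kinase_region: str,
    panel: ReferenceKinasePanel,
    min_score: float = DEFAULT_THRESHOLDS.subgroup_min_score,
) -> str:
    """Best-hit subgroup assignment of a kinase-domain region.

    Returns the label of the panel entry with the highest local alignment
    score, provided that score reaches `min_score`; otherwise
    ``"unclassified"``.  Ties keep the earliest panel entry.
    """
    if len(panel) == 0:
        raise ValueError("empty reference panel")
    best_label, best_score = "unclassified", -1.0
    for label, seq in panel.entries:
        s = local_align_score(kinase_region, seq)
        if s > best_score:
            best_label, best_score = label, s
    if best_score < min_score:
        return "unclassified"
    return best_label


@dataclass
class RepertoireResult:
    """Output of :func:`identify_repertoire` for one proteome."""

    calls: list
    counts: dict
    searched_total: int
    subgroup_counts: dict
    multi_family: list

    def count(self, family: str) -> int:
        return self.counts.get(family, 0)


def identify_repertoire(
    proteome: Sequence[ProteinRecord],
    hits: Sequence[DomainHit],
    tm_table: Optional[Mapping[str, TmRecord]] = None,
    t: RuleThresholds = DEFAULT_THRESHOLDS,
    panel: Optional[ReferenceKinasePanel] = None,
) -> RepertoireResult:
    """Classify every protein of a primary-transcript proteome.

    Applies the four family rules independently to each protein (a protein
    satisfying several rules is counted in every family it matches; such
    multi-family proteins are reported separately).  The searched-gene total
    is the number of primary transcripts, i.e. ``len(proteome)``.  When a
    reference panel is given, every LRR-RLK call gets a subgroup label.
    """
    hits_by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        hits_by_protein.setdefault(h.protein_id, []).append(h)
    tm_table = tm_table or {}

    calls: list[ReceptorCall] = []
    counts = {f: 0 for f in FAMILIES}
    subgroup_counts: dict[str, int] = {}
    multi: list[str] = []

    for p in proteome:
        ph = hits_by_protein.get(p.protein_id, ())
        tm = tm_table.get(p.protein_id)
        families = []
        if classify_lrr_rlk(p, ph, t):
            families.append("LRR-RLK")
        if classify_lrr_rlp(p, ph, tm, t):
            families.append("LRR-RLP")
        if classify_nbarc(p, ph, t):
            families.append("NB-ARC")
        lysm = classify_lysm(p, ph, tm, t)
        if lysm:
            families.append(lysm)
        if len(families) > 1:
            multi.append(p.protein_id)
        for fam in families:
            subgroup = None
            if fam == "LRR-RLK":
                if panel is not None:
                    region = extract_kinase_region(p, ph, t)
                    subgroup = assign_subgroup(region, panel, t.subgroup_min_score)
                else:
                    subgroup = "unclassified"
                subgroup_counts[subgroup] = subgroup_counts.get(subgroup, 0) + 1
            calls.append(ReceptorCall(p.protein_id, fam, subgroup))
            counts[fam] += 1

    if multi:
        logger.info("%d protein(s) matched more than one family: %s",
                    len(multi), multi[:20])
    return RepertoireResult(
        calls=calls,
        counts=counts,
        searched_total=len(proteome),
        subgroup_counts=subgroup_counts,
        multi_family=multi,
    )
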