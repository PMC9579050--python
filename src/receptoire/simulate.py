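"""Synthetic proteomes, hit tables, gene maps and trees with known truth.

The generator emulates the statistical structure the comparative analysis
assumes, at a scale a single CPU handles in seconds per replicate:

* **Counts.** Per-species receptor counts follow a Poisson log-linear
  latent-factor model: a species-level factor ``z_s ~ N(0, 1)`` (think of it
  as the species' overall investment in immunity) enters every family's
  log-rate, ``N_fs ~ Poisson(exp(a_f + b_f z_s))``.  Shared positive
  loadings ``b_f`` induce positive correlation between family percentages;
  :func:`calibrate_loading` solves the closed-form moment equations so a
  chosen family pair hits a target Pearson correlation on the percentage
  scale.
* **Proteomes.** Every planted receptor gets a protein record plus domain
  hit/TM rows that satisfy exactly one family rule, with E-values sampled
  well inside the thresholds; decoys fail every rule in varied ways
  (missing domains, sub-threshold E-values, short lengths).  Boundary cases
  at every threshold (250/249 AA, 150/149 AA, E exactly at the cut-off,
  C3F alignment 140/139) are planted so tests pin the inclusive-on-pass
  comparisons.
* **Coordinates.** Genes are placed uniformly on a chromosome; a configured
  fraction of group-A genes is instead planted within a window of an
  NB-ARC gene, creating genomic clusters of known strength.
* **Tree.** A pure-birth (Yule) species tree; optionally the latent factor
  evolves by Brownian motion along it, giving the percentages phylogenetic
  signal of known strength.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import dendropy
import random as _pyrandom

from scipy.optimize import brentq

from receptoire.io import DomainHit, GeneLocus, ProteinRecord, TmRecord
from receptoire.rules import (
    DEFAULT_LRR_ACCS,
    LRR_RLK_SUBGROUPS,
    ReferenceKinasePanel,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedProteome",
    "simulate_counts",
    "simulate_proteome",
    "simulate_tree",
    "brownian_trait",
    "calibrate_loading",
    "make_reference_panel",
    "percentage_correlation",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_FAMILIES = ("LRR-RLK", "LRR-RLP", "LysM-RLK", "LysM-RLP", "NB-ARC")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe a 300-species angiosperm-like cohort at a desk scale:
    mean receptor counts of a few dozen per family in proteomes of several
    hundred searched genes, with loadings calibrated for a strong (r = 0.8)
    percentage correlation between NB-ARC and LRR-RLP repertoires.
    """

    n_species: int = 300
    families: tuple = DEFAULT_FAMILIES
    #: per-family baseline log-rates a_f (mean count = exp(a_f) at z = 0).
    #: The correlated NB-ARC / LRR-RLP pair gets large baselines so its
    #: percentage distributions stay close to normal (small loading suffices
    #: for a strong correlation); the remaining families stay small.
    log_rates: tuple = (
        math.log(60.0),  # LRR-RLK
        math.log(80.0),  # LRR-RLP
        math.log(7.0),   # LysM-RLK
        math.log(2.5),   # LysM-RLP
        math.log(200.0),  # NB-ARC
    )
    #: latent-factor loadings b_f; overridden for `target_pair` when
    #: `target_r` is set
    loadings: tuple = (0.2, 0.25, 0.15, 0.15, 0.25)
    #: searched-proteome size range (uniform integer draw, inclusive); kept
    #: narrow so the shared denominator contributes negligible covariance
    #: between family percentages (the latent factor, not the proteome size,
    #: must carry the correlation), and well above the planted-count tail so
    #: the searched total never collides with the planted sum
    proteome_size_range: tuple = (900, 940)
    #: calibrate the loading shared by this family pair to hit `target_r`
    target_r: Optional[float] = None
    target_pair: tuple = ("NB-ARC", "LRR-RLP")
    #: genomic clustering of group A near NB-ARC genes
    clustering_fraction: float = 0.0
    clustering_window: int = 50_000
    cluster_group: str = "LRR-RLK"
    chromosome_length: int = 10_000_000
    n_chromosomes: int = 1
    gene_length_range: tuple = (2_000, 6_000)
    #: Yule birth rate for the species tree
    birth_rate: float = 1.0
    #: Brownian variance per unit branch length for the latent factor;
    #: None keeps z i.i.d. across species (no phylogenetic signal)
    brownian_variance: Optional[float] = None
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 3:
            raise ValueError("n_species must be >= 3")
        if not all(np.isfinite(self.loadings)):
            raise ValueError("loadings must be finite")
        if not 0.0 <= self.clustering_fraction <= 1.0:
            raise ValueError("clustering_fraction must lie in [0, 1]")
        if self.clustering_window <= 0:
            raise ValueError("clustering_window must be positive")
        lo, hi = self.proteome_size_range
        if lo < 1 or hi < lo:
            raise ValueError("bad proteome_size_range")
        # guard against overflowing Poisson rates
        for a, b in zip(self.log_rates, self.loadings):
            if a + 8 * abs(b) > 50:
                raise ValueError("log-rate + loading implies overflowing rates")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    counts: Optional[pd.DataFrame] = None
    totals: Optional[pd.Series] = None
    latent: Optional[pd.Series] = None
    #: protein_id -> planted family (decoys absent)
    family_of: dict = field(default_factory=dict)
    #: protein_id -> planted LRR-RLK subgroup
    subgroup_of: dict = field(default_factory=dict)
    #: gene ids planted inside a cluster window of an NB-ARC gene
    clustered_genes: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Counts


def _uniform_inv_moments(lo: float, hi: float) -> tuple[float, float]:
    """E[1/T] and E[1/T^2] for T ~ Uniform(lo, hi)."""
    width = hi - lo
    if width == 0:
        return 1.0 / lo, 1.0 / lo**2
    return math.log(hi / lo) / width, (1.0 / lo - 1.0 / hi) / width


def percentage_correlation(
    a1: float, a2: float, b1: float, b2: float, size_range: tuple
) -> float:
    """Closed-form Pearson correlation between two family percentages.

    Uses lognormal moments of the latent rates and exact inverse moments of
    the uniform proteome size; counts are conditionally independent Poisson
    given the latent factor.
    """
    m1, m2 = _uniform_inv_moments(*size_range)
    mu1 = math.exp(a1 + b1**2 / 2)
    mu2 = math.exp(a2 + b2**2 / 2)
    e_n1sq = mu1 + math.exp(2 * a1 + 2 * b1**2)
    e_n2sq = mu2 + math.exp(2 * a2 + 2 * b2**2)
    e_n1n2 = math.exp(a1 + a2 + (b1**2 + b2**2) / 2 + b1 * b2)
    ep1 = mu1 * m1
    ep2 = mu2 * m1
    var1 = e_n1sq * m2 - ep1**2
    var2 = e_n2sq * m2 - ep2**2
    cov = e_n1n2 * m2 - ep1 * ep2
    return cov / math.sqrt(var1 * var2)


def calibrate_loading(
    a1: float,
    a2: float,
    size_range: tuple,
    target_r: float,
    max_loading: float = 3.0,
) -> float:
    """Shared loading b such that the two families' percentages correlate at
    `target_r` (closed-form moment matching, solved by root bracketing)."""
    if not 0 < target_r < 1:
        raise ValueError("target_r must lie in (0, 1)")

    def f(b):
        return percentage_correlation(a1, a2, b, b, size_range) - target_r

    lo = 1e-6
    if f(max_loading) < 0:
        raise ValueError(
            f"target r = {target_r} unreachable with loading <= {max_loading}"
        )
    return float(brentq(f, lo, max_loading, xtol=1e-10))


def _resolved_loadings(cfg: SimulationConfig) -> np.ndarray:
    loadings = np.array(cfg.loadings, dtype=float)
    if cfg.target_r is not None:
        i = cfg.families.index(cfg.target_pair[0])
        j = cfg.families.index(cfg.target_pair[1])
        a = cfg.log_rates
        b = calibrate_loading(a[i], a[j], cfg.proteome_size_range, cfg.target_r)
        loadings[i] = loadings[j] = b
    return loadings


def simulate_counts(
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    latent: Optional[pd.Series] = None,
) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Draw per-species family counts and searched totals.

    Returns ``(counts, totals, truth)``; species are labelled ``sp0001``...
    A precomputed `latent` series (e.g. evolved on a tree by
    :func:`brownian_trait`) overrides the i.i.d. standard-normal factor.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    species = [f"sp{i + 1:04d}" for i in range(cfg.n_species)]
    if latent is None:
        z = pd.Series(rng.standard_normal(cfg.n_species), index=species)
    else:
        z = latent.loc[species] if set(species) <= set(latent.index) else latent
        species = list(z.index)
    loadings = _resolved_loadings(cfg)
    rates = np.exp(
        np.add.outer(z.values, np.zeros(len(cfg.families)))
        * loadings[None, :]
        + np.array(cfg.log_rates)[None, :]
    )
    counts = pd.DataFrame(
        rng.poisson(rates), index=species, columns=list(cfg.families)
    )
    lo, hi = cfg.proteome_size_range
    totals = pd.Series(rng.integers(lo, hi + 1, size=len(species)), index=species)
    # the searched total can never be smaller than what was planted
    totals = pd.concat([totals, counts.sum(axis=1)], axis=1).max(axis=1)
    truth = GroundTruth(counts=counts, totals=totals, latent=z)
    return counts, totals, truth


# ---------------------------------------------------------------------------
# Proteomes

_LRR_ACCS = sorted(DEFAULT_LRR_ACCS)


def _rand_seq(pool: str, rng: np.random.Generator, length: int) -> str:
    off = int(rng.integers(0, len(pool) - length))
    return pool[off : off + length]


_AA20_CODES = np.frombuffer(_AA20.encode("ascii"), dtype=np.uint8)


def _make_pool(rng: np.random.Generator, size: int = 100_000) -> str:
    idx = rng.integers(0, len(_AA20_CODES), size=size)
    return _AA20_CODES[idx].tobytes().decode("ascii")


def _loghit(
    rng: np.random.Generator,
    pid: str,
    acc: str,
    log10_e: tuple,
    start: int,
    end: int,
    bitscore: Optional[float] = None,
) -> DomainHit:
    e = 10.0 ** rng.uniform(*log10_e)
    return DomainHit(
        protein_id=pid, pfam_acc=acc, seq_evalue=e, dom_evalue=e,
        bitscore=bitscore if bitscore is not None else float(rng.uniform(60, 400)),
        ali_start=start, ali_end=end, env_start=start, env_end=end,
    )


@dataclass
class SimulatedProteome:
    """In-memory synthetic proteome for one species."""

    species_id: str
    proteins: list
    hits: list
    tm: dict
    loci: list
    truth: GroundTruth


def _plant_receptor(
    family: str,
    pid: str,
    rng: np.random.Generator,
    pool: str,
    panel: Optional[ReferenceKinasePanel],
    subgroup: Optional[str],
    boundary: bool,
    species_id: str,
) -> tuple[ProteinRecord, list, TmRecord]:
    """One protein + hit rows satisfying exactly `family`'s rule."""
    hits: list[DomainHit] = []
    n_tm = 1
    if family == "LRR-RLK":
        length = 250 if boundary else int(rng.integers(300, 1100))
        kin_start = max(1, length - 290)
        kin_end = min(length, kin_start + 270)
        seq = _rand_seq(pool, rng, length)
        if panel is not None and subgroup is not None:
            ref = dict_panel(panel).get(subgroup)
            region = _mutate(ref, rng, rate=float(rng.uniform(0.0, 0.15)))
            kin_end = min(length, kin_start + len(region) - 1)
            region = region[: kin_end - kin_start + 1]
            seq = seq[: kin_start - 1] + region + seq[kin_end:]
            seq = seq[:length]
        e_kin = (-10.0, -10.0) if boundary else (-40.0, -15.0)
        hits.append(_loghit(rng, pid, "PF00069.26", e_kin, kin_start, kin_end))
        lrr_acc = _LRR_ACCS[int(rng.integers(len(_LRR_ACCS)))]
        e_lrr = (-2.0, -2.0) if boundary else (-8.0, -3.0)
        hits.append(_loghit(rng, pid, lrr_acc + ".7", e_lrr, 30, 120))
    elif family == "LRR-RLP":
        length = 150 if boundary else int(rng.integers(300, 900))
        seq = _rand_seq(pool, rng, length)
        lrr_acc = _LRR_ACCS[int(rng.integers(len(_LRR_ACCS)))]
        hits.append(_loghit(rng, pid, lrr_acc + ".7", (-8.0, -3.0), 20,
                            min(110, length - 1)))
        ali_len = 140 if boundary else int(rng.integers(140, 200))
        c3f_start = max(1, length - ali_len - 5)
        hits.append(
            _loghit(rng, pid, "C3F", (-10.0, -10.0) if boundary else (-30.0, -12.0),
                    c3f_start, c3f_start + ali_len - 1)
        )
    elif family == "NB-ARC":
        length = 150 if boundary else int(rng.integers(400, 1300))
        seq = _rand_seq(pool, rng, length)
        e_nb = (-10.0, -10.0) if boundary else (-60.0, -15.0)
        hits.append(_loghit(rng, pid, "PF00931.23", e_nb, 10,
                            min(140, length - 1)))
        n_tm = 0
    elif family in ("LysM-RLK", "LysM-RLP"):
        length = 150 if boundary else int(rng.integers(280, 700))
        seq = _rand_seq(pool, rng, length)
        hits.append(_loghit(rng, pid, "PF01476.21", (-8.0, 1.5), 5,
                            min(50, length - 1)))
        if family == "LysM-RLK":
            ks = max(1, length - 280)
            hits.append(_loghit(rng, pid, "PF00069.26", (-40.0, -15.0), ks,
                                min(length, ks + 260)))
    else:
        raise ValueError(f"unknown family {family!r}")
    rec = ProteinRecord(pid, pid.rsplit(".", 1)[0], species_id, seq)
    return rec, hits, TmRecord(pid, n_tm)


_DECOY_KINDS = (
    "no-hits", "kinase-only", "lrr-only", "lrr-c3f-no-tm", "weak-evalues",
    "short",
)


def _plant_decoy(
    kind: str, pid: str, rng: np.random.Generator, pool: str, species_id: str
) -> tuple[ProteinRecord, list, TmRecord]:
    """One protein guaranteed to fail every family rule."""
    hits: list[DomainHit] = []
    n_tm = 0
    if kind == "no-hits":
        length = int(rng.integers(150, 600))
    elif kind == "kinase-only":
        # kinase but no LRR: fails LRR-RLK; TM present but no LysM/C3F
        length = int(rng.integers(300, 800))
        hits.append(_loghit(rng, pid, "PF00069.26", (-40.0, -15.0), 20, 290))
        n_tm = 1
    elif kind == "lrr-only":
        # LRR but no kinase/C3F: fails both LRR rules
        length = int(rng.integers(300, 800))
        acc = _LRR_ACCS[int(rng.integers(len(_LRR_ACCS)))]
        hits.append(_loghit(rng, pid, acc + ".7", (-8.0, -3.0), 20, 110))
    elif kind == "lrr-c3f-no-tm":
        length = int(rng.integers(300, 800))
        acc = _LRR_ACCS[int(rng.integers(len(_LRR_ACCS)))]
        hits.append(_loghit(rng, pid, acc + ".7", (-8.0, -3.0), 20, 110))
        hits.append(_loghit(rng, pid, "C3F", (-30.0, -12.0), 120, 280))
        n_tm = 0
    elif kind == "weak-evalues":
        # every domain present but strictly above its threshold
        length = int(rng.integers(300, 800))
        hits.append(_loghit(rng, pid, "PF00069.26", (-9.5, -4.0), 20, 290))
        acc = _LRR_ACCS[int(rng.integers(len(_LRR_ACCS)))]
        hits.append(_loghit(rng, pid, acc + ".7", (-1.8, 0.5), 10, 100))
        # the kinase hit fails its own 1e-10 rule, so no LRR-RLK; the LRR hit
        # fails 1e-2; NB-ARC hit above 1e-10 fails too
        hits.append(_loghit(rng, pid, "PF00931.23", (-9.5, -4.0), 30, 160))
    elif kind == "short":
        # boundary-failing lengths: 249 AA with kinase+LRR, 149 AA with NB-ARC
        if rng.random() < 0.5:
            length = 249
            hits.append(_loghit(rng, pid, "PF00069.26", (-40.0, -15.0), 5, 240))
            acc = _LRR_ACCS[int(rng.integers(len(_LRR_ACCS)))]
            hits.append(_loghit(rng, pid, acc + ".7", (-8.0, -3.0), 3, 60))
            n_tm = 1
        else:
            length = 149
            hits.append(_loghit(rng, pid, "PF00931.23", (-60.0, -15.0), 5, 120))
    else:
        raise ValueError(kind)
    # a C3F alignment of 139 residues also never qualifies
    if kind == "lrr-only" and rng.random() < 0.3:
        hits.append(_loghit(rng, pid, "C3F", (-30.0, -12.0), 120, 120 + 139 - 1))
        n_tm = 1
    seq = _rand_seq(pool, rng, length)
    rec = ProteinRecord(pid, pid.rsplit(".", 1)[0], species_id, seq)
    return rec, hits, TmRecord(pid, n_tm)


def _place_genes(
    proteins: Sequence[ProteinRecord],
    truth: GroundTruth,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    species_id: str,
) -> list:
    """Gene coordinates: uniform placement with optional planted clustering."""
    loci = []
    nbarc_positions: list[tuple[str, int]] = []
    glo, ghi = cfg.gene_length_range
    chroms = [f"{species_id}_chr{c + 1}" for c in range(cfg.n_chromosomes)]

    def uniform_locus(gene_id):
        chrom = chroms[int(rng.integers(cfg.n_chromosomes))]
        glen = int(rng.integers(glo, ghi))
        start = int(rng.integers(1, cfg.chromosome_length - glen))
        return GeneLocus(gene_id, chrom, start, start + glen - 1,
                         "+" if rng.random() < 0.5 else "-")

    cluster_candidates = []
    for p in proteins:
        fam = truth.family_of.get(p.protein_id)
        if fam == cfg.cluster_group and cfg.clustering_fraction > 0:
            cluster_candidates.append(p)
            continue
        loc = uniform_locus(p.gene_id)
        loci.append(loc)
        if fam == "NB-ARC":
            nbarc_positions.append((loc.seq_id, loc.start))

    for p in cluster_candidates:
        glen = int(rng.integers(glo, ghi))
        if nbarc_positions and rng.random() < cfg.clustering_fraction:
            seq_id, anchor = nbarc_positions[int(rng.integers(len(nbarc_positions)))]
            offset = int(rng.integers(-cfg.clustering_window, cfg.clustering_window + 1))
            start = min(max(1, anchor + offset), cfg.chromosome_length - glen)
            loci.append(GeneLocus(p.gene_id, seq_id, start, start + glen - 1, "+"))
            truth.clustered_genes.append(p.gene_id)
        else:
            loci.append(uniform_locus(p.gene_id))
    return loci


def simulate_proteome(
    species_counts: pd.Series,
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    total: Optional[int] = None,
    panel: Optional[ReferenceKinasePanel] = None,
    include_boundaries: bool = True,
    with_loci: bool = True,
) -> SimulatedProteome:
    """Emit one species' proteome, hit table, TM table and gene map.

    `species_counts` maps family name to planted count (one row of
    :func:`simulate_counts` output); `total` is the searched-proteome size
    (decoys fill the difference).  With `include_boundaries`, the first
    planted receptor of each family sits exactly at the inclusive threshold
    (length 250/150, E-value 1e-10/1e-2, C3F alignment 140) so tests pin the
    comparison direction.  When a reference panel is given, each planted
    LRR-RLK embeds a mutated copy of one panel kinase domain and records the
    planted subgroup.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    species_id = str(species_counts.name) if species_counts.name else "spX"
    pool = _make_pool(rng)
    truth = GroundTruth()
    proteins: list[ProteinRecord] = []
    hits: list[DomainHit] = []
    tm: dict[str, TmRecord] = {}
    k = 0
    for family in cfg.families:
        n_f = int(species_counts.get(family, 0))
        for i in range(n_f):
            k += 1
            pid = f"{species_id}_p{k:05d}.1"
            subgroup = None
            if family == "LRR-RLK" and panel is not None:
                subgroup = panel.entries[int(rng.integers(len(panel)))][0]
            rec, h, t = _plant_receptor(
                family, pid, rng, pool, panel, subgroup,
                boundary=(include_boundaries and i == 0), species_id=species_id,
            )
            proteins.append(rec)
            hits.extend(h)
            tm[pid] = t
            truth.family_of[pid] = family
            if subgroup is not None:
                truth.subgroup_of[pid] = subgroup
    planted = k
    n_total = int(total) if total is not None else planted + 100
    n_decoys = max(0, n_total - planted)
    for i in range(n_decoys):
        k += 1
        pid = f"{species_id}_p{k:05d}.1"
        if i < len(_DECOY_KINDS):
            kind = _DECOY_KINDS[i]  # one of each kind is always present
        elif rng.random() < 0.6:
            # the bulk of a real proteome carries none of these domains
            kind = "no-hits"
        else:
            kind = _DECOY_KINDS[int(rng.integers(len(_DECOY_KINDS)))]
        rec, h, t = _plant_decoy(kind, pid, rng, pool, species_id)
        proteins.append(rec)
        hits.extend(h)
        tm[pid] = t
    loci = _place_genes(proteins, truth, cfg, rng, species_id) if with_loci else []
    return SimulatedProteome(species_id, proteins, hits, tm, loci, truth)


# ---------------------------------------------------------------------------
# Trees and traits


def simulate_tree(cfg: SimulationConfig, seed: Optional[int] = None) -> dendropy.Tree:
    """Pure-birth (Yule) species tree with `cfg.n_species` extant tips.

    Leaf labels match the species ids of :func:`simulate_counts`.
    """
    from dendropy.simulate import treesim

    rng = _pyrandom.Random(cfg.seed if seed is None else seed)
    taxa = dendropy.TaxonNamespace(
        [f"sp{i + 1:04d}" for i in range(cfg.n_species)]
    )
    tree = treesim.birth_death_tree(
        birth_rate=cfg.birth_rate,
        death_rate=0.0,
        num_extant_tips=cfg.n_species,
        taxon_namespace=taxa,
        rng=rng,
    )
    return tree


def brownian_trait(
    tree: dendropy.Tree,
    variance_per_unit: float,
    seed: Optional[int] = None,
    root_value: float = 0.0,
) -> pd.Series:
    """Evolve a trait by Brownian motion along the tree.

    Returns the tip values, indexed by leaf label.  With variance 0 every
    tip inherits the root value.
    """
    rng = np.random.default_rng(seed)
    values: dict = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[node] = root_value
        else:
            edge = node.edge.length or 0.0
            step = rng.normal(0.0, math.sqrt(variance_per_unit * edge)) \
                if variance_per_unit > 0 and edge > 0 else 0.0
            values[node] = values[node.parent_node] + step
    return pd.Series(
        {leaf.taxon.label: values[leaf] for leaf in tree.leaf_node_iter()}
    )


# ---------------------------------------------------------------------------
# Reference panel


def dict_panel(panel: ReferenceKinasePanel) -> dict:
    """First panel sequence per subgroup label."""
    out = {}
    for label, seq in panel.entries:
        out.setdefault(label, seq)
    return out


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    """Point-mutate a fraction `rate` of residues (substitutions only)."""
    if rate <= 0:
        return seq
    chars = list(seq)
    n_mut = int(round(rate * len(chars)))
    pos = rng.choice(len(chars), size=min(n_mut, len(chars)), replace=False)
    for i in pos:
        chars[i] = _AA20[int(rng.integers(len(_AA20)))]
    return "".join(chars)


def make_reference_panel(
    seed: int = 0, region_length: int = 280, per_subgroup: int = 1
) -> ReferenceKinasePanel:
    """Synthetic subgroup reference panel (random kinase-domain stand-ins).

    One (or `per_subgroup`) random sequence per canonical subgroup.  Random
    unrelated sequences of this length are far apart under BLOSUM62 local
    alignment, so best-hit assignment against this synthetic panel behaves
    like assignment against a real reference set.
    """
    rng = np.random.default_rng(seed)
    pool = _make_pool(rng, size=60_000)
    entries = []
    for label in LRR_RLK_SUBGROUPS:
        for _ in range(per_subgroup):
            entries.append((label, _rand_seq(pool, rng, region_length)))
    return ReferenceKinasePanel(entries=entries)
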