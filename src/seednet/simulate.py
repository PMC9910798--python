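"""Synthetic inputs with planted, recoverable structure.

Everything the pipeline consumes can be generated here with known
ground truth: multi-source PPI evidence with planned publication and
method scores, negative-binomial RNA-seq counts for T tissues with a
planted tissue clade, planted differential expression, a planted
seed-co-expressed interactor subset driven by a shared latent factor,
samples with sub-threshold mapping rates, high-missingness genes, and a
gene-set collection with one planted enriched term plus terms sitting
exactly on the size-filter boundaries.

The default configuration mirrors the study design the pipeline
targets: 15 tissues (11 brain-like including a 3-tissue striatum-like
clade and a cerebellum-like tissue, 4 periphery-like), a seed gene with
a quality-scored interactome, high co-expression but low relative
expression in the clade, and the opposite in the cerebellum-like
tissue.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gct import CountMatrix
from .ppi import InteractionEvidence

__all__ = [
    "SimulationConfig",
    "PpiSimulation",
    "CountsSimulation",
    "AnnotationSimulation",
    "simulate_ppi_sources",
    "simulate_counts",
    "simulate_annotations",
    "calibrate_latent_weight",
    "write_all_inputs",
]

# PSI-MI detection-method grouping dictionary used by the simulator
# (real ontology codes; two-hybrid variants share one group).
DEFAULT_METHOD_DICTIONARY: dict[str, str] = {
    "MI:0399": "Two Hybrid",
    "MI:1113": "Two Hybrid",
    "MI:0018": "Two Hybrid",
    "MI:0004": "Affinity Chromatography",
    "MI:0096": "Affinity Chromatography",
    "MI:0006": "Affinity Chromatography",
    "MI:0416": "Imaging",
    "MI:0663": "Imaging",
    "MI:0401": "Biochemical",
    "MI:0415": "Biochemical",
    "MI:0030": "Cross-linking",
}

BRAIN_TISSUES = (
    "striatum_a", "striatum_b", "striatum_c", "cerebellum_like",
    "brain_05", "brain_06", "brain_07", "brain_08", "brain_09",
    "brain_10", "brain_11",
)
PERIPHERY_TISSUES = ("lung_like", "liver_like", "kidney_like", "blood_like")


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the study conditions."""

    rng_seed: int = 0
    seed_symbol: str = "SEED1"

    # gene / interactome universe
    n_genes: int = 2000            # must exceed the 1501 term-size boundary
    n_interactors: int = 65        # FS > 2 survivors in the PPI plan
    n_low_fs: int = 15             # planted FS <= 2 interactors (filtered out)
    n_members_absent: int = 2      # survivors missing from the count matrix
    n_high_missing: int = 3        # survivors failing the 5% zero-count rule

    # counts
    n_tissues: int = 15
    samples_per_tissue: int = 50
    nb_dispersion: float = 0.1
    base_log_mean: float = float(np.log(100.0))
    base_log_sd: float = 1.0
    member_base_log_sd: float = 0.8
    member_base_floor: float = 3.0   # keeps members clear of the zero filter
    brain_effect_sd: float = 0.4
    tissue_effect_sd: float = 0.25
    clade_mean_shift: float = -0.4   # low relative expression in the clade
    clade_effect_sd: float = 0.3
    clade_member_noise_sd: float = 0.05
    de_tissue: str = "cerebellum_like"
    n_de: int = 10
    de_fold: float = 4.0
    planted_clade: tuple[str, ...] = ("striatum_a", "striatum_b", "striatum_c")

    # planted co-expression
    n_coex: int = 20
    coex_target_r: float = 0.8
    coex_base_floor: float = 4.2   # co-expressed partners of a strong hub
                                   # stay well-expressed in the clade
    seed_base_floor: float = 5.0   # the hub itself is robustly expressed

    # planted expression-profile twins of the seed (DEA cluster recovery)
    n_seed_profile: int = 15
    seed_profile_base_sd: float = 0.1
    seed_profile_noise_sd: float = 0.05

    # QC pathologies
    n_low_rate_samples: int = 2
    mapping_rate_beta: tuple[float, float] = (80.0, 4.0)

    # annotations
    n_background_terms: int = 25
    planted_term_overlap: int = 30

    def __post_init__(self) -> None:
        if not 0 < self.coex_target_r < 1:
            raise ValueError("coex_target_r must be in (0, 1)")
        if self.de_fold <= 0:
            raise ValueError("fold changes must be positive")
        analysed = self.n_interactors - self.n_members_absent - self.n_high_missing
        for name, size in (
            ("n_coex", self.n_coex),
            ("n_de", self.n_de),
            ("n_seed_profile", self.n_seed_profile),
        ):
            if size > analysed:
                raise ValueError(f"{name}={size} exceeds analysed members ({analysed})")
        if self.n_tissues != len(self.tissues):
            raise ValueError("n_tissues must match the tissue label plan (15)")
        if set(self.planted_clade) - set(self.tissues):
            raise ValueError("planted clade must be a subset of the tissues")

    @property
    def tissues(self) -> list[str]:
        return list(BRAIN_TISSUES) + list(PERIPHERY_TISSUES)

    @property
    def brain_tissues(self) -> list[str]:
        return list(BRAIN_TISSUES)

    @property
    def gene_symbols(self) -> list[str]:
        return [self.seed_symbol] + [f"G{i:04d}" for i in range(1, self.n_genes)]

    @property
    def interactor_symbols(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.n_interactors + 1)]

    @property
    def low_fs_symbols(self) -> list[str]:
        start = self.n_interactors + 1
        return [f"G{i:04d}" for i in range(start, start + self.n_low_fs)]


def _as_jsonable(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    return obj


@dataclass
class GroundTruthMixin:
    def to_json(self, path: str | Path) -> None:
        payload = _as_jsonable(asdict(self))
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# PPI evidence
# ---------------------------------------------------------------------------

_SOURCES = ("sourceA", "sourceB", "sourceC")
_NAMESPACES = {"sourceA": "symbol", "sourceB": "entrez", "sourceC": "uniprot"}


@dataclass
class PpiTruth(GroundTruthMixin):
    expected_scores: dict[str, tuple[int, int, int]]  # symbol -> (PS, MS, FS)
    survivors: list[str]
    source_membership: dict[str, list[str]]
    dropped_obsolete: list[str]
    dropped_unreviewed: list[str]


@dataclass
class PpiSimulation:
    evidence: dict[str, pd.DataFrame]          # source label -> table
    id_mapping: pd.DataFrame
    method_dictionary: dict[str, str]
    truth: PpiTruth

    def evidence_records(self) -> list[list[InteractionEvidence]]:
        """In-memory equivalent of parsing each source table."""
        lists = []
        for source, frame in self.evidence.items():
            records = [
                InteractionEvidence(
                    source_db=source,
                    interactor_raw_id=row.interactor_id,
                    id_namespace=row.namespace,
                    publication_id=row.publication_id or None,
                    method_code=row.method_code or None,
                    method_label=row.method_label or None,
                )
                for row in frame.itertuples()
            ]
            lists.append(records)
        return lists


def _raw_id(symbol: str, namespace: str) -> str:
    if namespace == "symbol":
        return symbol
    digits = symbol[1:] if symbol[0] == "G" else "0000"
    if namespace == "entrez":
        return f"9{digits}"
    return f"Q{digits}XX"


def simulate_ppi_sources(config: SimulationConfig) -> PpiSimulation:
    """Three-source evidence plan with exact expected PS/MS/FS.

    Each planned interactor gets ``PS`` distinct publications and
    evidence codes spanning ``MS`` method groups; items are duplicated
    across the interactor's sources so cross-database duplicates are
    planted. One obsolete and one unreviewed identifier are included to
    exercise harmonization drops.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 101]))
    groups: dict[str, list[str]] = {}
    for code, group in DEFAULT_METHOD_DICTIONARY.items():
        groups.setdefault(group, []).append(code)
    group_names = sorted(groups)

    rows: dict[str, list[dict]] = {s: [] for s in _SOURCES}
    mapping_rows: list[dict] = []
    expected: dict[str, tuple[int, int, int]] = {}
    membership: dict[str, list[str]] = {}

    def plan_interactor(symbol: str, ps: int, ms: int, sources: list[str]) -> None:
        if ms > len(group_names):
            raise ValueError(
                f"plan requests {ms} method groups, dictionary holds {len(group_names)}"
            )
        pubs = [f"pmid:{symbol}:{k}" for k in range(ps)]
        chosen_groups = list(rng.choice(group_names, size=ms, replace=False)) if ms else []
        n_items = max(ps, ms, 1)
        items = []
        for k in range(n_items):
            pub = pubs[k % ps] if ps else ""
            if ms:
                group = chosen_groups[k % ms]
                code = str(rng.choice(groups[group]))
            else:
                code = ""
            items.append((pub, code))
        used: set[str] = set()
        placements = []
        for item in items:
            carriers = [s for s in sources if rng.random() < 0.6]
            if not carriers:
                carriers = [str(rng.choice(sources))]
            placements.append((item, carriers))
            used.update(carriers)
        for source in sources:  # every planned source carries >= 1 item
            if source not in used:
                placements.append((items[0], [source]))
        for (pub, code), carriers in placements:
            for source in carriers:
                namespace = _NAMESPACES[source]
                rows[source].append(
                    {
                        "interactor_id": _raw_id(symbol, namespace),
                        "namespace": namespace,
                        "publication_id": pub,
                        "method_code": code,
                        "method_label": DEFAULT_METHOD_DICTIONARY.get(code, ""),
                    }
                )
        expected[symbol] = (ps, ms, ps + ms)
        membership[symbol] = sorted(sources)
        for namespace in {_NAMESPACES[s] for s in sources}:
            mapping_rows.append(
                {
                    "raw_id": _raw_id(symbol, namespace),
                    "namespace": namespace,
                    "gene_symbol": symbol,
                    "reviewed": "true",
                    "obsolete": "false",
                }
            )

    # seed self-interaction: robustly replicated
    plan_interactor(config.seed_symbol, ps=6, ms=4, sources=list(_SOURCES))

    for symbol in config.interactor_symbols:
        ps = int(rng.integers(1, 6))
        ms = int(rng.integers(1, 5))
        if ps + ms <= 2:  # survivors must clear FS > 2
            ps += 2
        n_sources = int(rng.choice([1, 2, 3], p=[0.25, 0.45, 0.30]))
        sources = list(rng.choice(_SOURCES, size=n_sources, replace=False))
        plan_interactor(symbol, ps, ms, sources)

    for i, symbol in enumerate(config.low_fs_symbols):
        source = [_SOURCES[i % 3]]
        if i % 3 == 0:
            plan_interactor(symbol, ps=1, ms=1, sources=source)  # FS = 2
        elif i % 3 == 1:
            plan_interactor(symbol, ps=0, ms=1, sources=source)  # missing pubs
        else:
            plan_interactor(symbol, ps=1, ms=0, sources=source)  # missing methods

    # obsolete and unreviewed identifiers (dropped during harmonization)
    rows["sourceB"].append(
        {
            "interactor_id": "9999999", "namespace": "entrez",
            "publication_id": "pmid:11111", "method_code": "MI:0004",
            "method_label": "Affinity Chromatography",
        }
    )
    mapping_rows.append(
        {"raw_id": "9999999", "namespace": "entrez", "gene_symbol": "",
         "reviewed": "true", "obsolete": "true"}
    )
    rows["sourceA"].append(
        {
            "interactor_id": "READTHROUGH1", "namespace": "symbol",
            "publication_id": "pmid:22222", "method_code": "MI:0399",
            "method_label": "Two Hybrid",
        }
    )
    mapping_rows.append(
        {"raw_id": "READTHROUGH1", "namespace": "symbol",
         "gene_symbol": "READTHROUGH1", "reviewed": "false", "obsolete": "false"}
    )

    evidence = {
        source: pd.DataFrame(
            table,
            columns=["interactor_id", "namespace", "publication_id",
                     "method_code", "method_label"],
        )
        for source, table in rows.items()
    }
    truth = PpiTruth(
        expected_scores=expected,
        survivors=sorted(
            [s for s, (_, _, fs) in expected.items() if fs > 2]
        ),
        source_membership=membership,
        dropped_obsolete=["9999999"],
        dropped_unreviewed=["READTHROUGH1"],
    )
    mapping = pd.DataFrame(mapping_rows).drop_duplicates(
        subset=["raw_id", "namespace"]
    )
    return PpiSimulation(evidence, mapping, dict(DEFAULT_METHOD_DICTIONARY), truth)


# ---------------------------------------------------------------------------
# latent-factor weight calibration
# ---------------------------------------------------------------------------

_CALIBRATION_CACHE: dict[tuple, float] = {}


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    size = 1.0 / alpha
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def _realized_r(w_a: float, w_b: float, base_a: float, base_b: float,
                alpha: float, n: int, rng: np.random.Generator,
                replicates: int = 1) -> float:
    """Mean sample correlation of a latent-factor NB pair.

    Averaged over replicates of size ``n``: the log-scale latent factor
    makes single-draw correlations heavy-tail sensitive, and the mean of
    bounded per-replicate estimates is far more stable than one huge
    draw.
    """
    out = []
    for _ in range(replicates):
        z = rng.normal(size=n)
        mu_a = np.exp(base_a + w_a * z - w_a**2 / 2)
        mu_b = np.exp(base_b + w_b * z - w_b**2 / 2)
        a = _nb_draw(rng, mu_a, alpha)
        b = _nb_draw(rng, mu_b, alpha)
        out.append(np.corrcoef(a, b)[0, 1])
    return float(np.mean(out))


def calibrate_latent_weight(
    target_r: float,
    base_a: float,
    base_b: float,
    dispersion: float,
    n_calibration: int = 4000,
    w_fixed: float | None = None,
) -> float:
    """Latent-factor weight achieving a target count-scale Pearson r.

    The correlation between two negative-binomial genes sharing a
    log-scale latent factor has no convenient closed form, so the weight
    is found empirically: realized r is measured on a large calibration
    draw over a weight grid and the crossing is interpolated. With
    ``w_fixed`` the partner gene's weight is held at that value and only
    gene ``a``'s weight is searched (used for per-gene calibration
    against the seed). Cached per rounded (target, bases, dispersion,
    w_fixed) key; the calibration RNG is fixed so results do not depend
    on the caller's seed.
    """
    key = (round(target_r, 3), round(base_a, 2), round(base_b, 2),
           round(dispersion, 4),
           None if w_fixed is None else round(w_fixed, 3))
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]
    rng = np.random.default_rng(20240917)
    grid = np.linspace(0.2, 1.4, 13)
    replicates = max(1, n_calibration // 100)
    realized = np.array([
        _realized_r(w, w if w_fixed is None else w_fixed,
                    base_a, base_b, dispersion, 100, rng,
                    replicates=replicates)
        for w in grid
    ])
    # enforce monotonicity before inverting the curve
    realized = np.maximum.accumulate(realized)
    w = float(np.interp(target_r, realized, grid))
    w = float(np.clip(w, grid[0], grid[-1]))
    _CALIBRATION_CACHE[key] = w
    return w


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


@dataclass
class CountsTruth(GroundTruthMixin):
    planted_clade: list[str]
    coex_set: list[str]
    coex_target_r: float
    latent_weight: float                 # the seed gene's weight
    latent_weights: dict[str, float]     # per planted interactor
    de_genes: list[str]
    de_tissue: str
    de_fold: float
    seed_profile_set: list[str]
    low_rate_samples: list[str]
    high_missing_genes: list[str]
    absent_members: list[str]
    analysed_members: list[str]


@dataclass
class CountsSimulation:
    matrix: CountMatrix
    truth: CountsTruth


def simulate_counts(config: SimulationConfig) -> CountsSimulation:
    """Negative-binomial counts with every planted feature of the design.

    Per gene g, tissue t, sample j the log mean is::

        base_g + brain_g * [t is brain] + offset_{g,t} + de_{g,t}
               + w * z_j - w^2 / 2      (seed + co-expressed set, clade only)

    with offsets shared across the planted clade (plus small per-tissue
    noise) so the clade is recoverable as a dendrogram clade, a global
    positive shift in the DE tissue, and the latent factor ``z`` drawn
    per sample. The ``- w^2/2`` term centres the latent factor so
    planting co-expression does not plant differential expression.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 202]))
    tissues = config.tissues
    genes = config.gene_symbols
    n_genes = len(genes)
    gene_index = {g: i for i, g in enumerate(genes)}

    members = list(config.interactor_symbols)
    absent = [str(g) for g in rng.choice(members, size=config.n_members_absent, replace=False)]
    remaining = [g for g in members if g not in set(absent)]
    high_missing = [str(g) for g in rng.choice(remaining, size=config.n_high_missing, replace=False)]
    analysed = [g for g in remaining if g not in set(high_missing)]
    coex_set = [str(g) for g in rng.choice(analysed, size=config.n_coex, replace=False)]
    non_coex = [g for g in analysed if g not in set(coex_set)]
    de_genes = [str(g) for g in rng.choice(non_coex, size=config.n_de, replace=False)]
    rest = [g for g in non_coex if g not in set(de_genes)]
    seed_profile = [str(g) for g in rng.choice(rest, size=config.n_seed_profile, replace=False)]

    keep_genes = [g for g in genes if g not in set(absent)]

    # base log means; interactome members kept clear of the low-count filter
    base = rng.normal(config.base_log_mean, config.base_log_sd, size=n_genes)
    member_mask = np.zeros(n_genes, dtype=bool)
    for g in members + [config.seed_symbol]:
        member_mask[gene_index[g]] = True
    base[member_mask] = np.maximum(
        rng.normal(config.base_log_mean, config.member_base_log_sd,
                   size=member_mask.sum()),
        config.member_base_floor,
    )
    base[gene_index[config.seed_symbol]] = max(
        base[gene_index[config.seed_symbol]], config.seed_base_floor
    )

    brain = rng.normal(0.0, config.brain_effect_sd, size=n_genes)
    # planted uniquely-high genes are brain/periphery-neutral: their tissue
    # specificity must come from the planted fold alone
    for g in de_genes:
        brain[gene_index[g]] = 0.0
    clade_shared = rng.normal(config.clade_mean_shift, config.clade_effect_sd,
                              size=n_genes)
    offsets = {}
    for tissue in tissues:
        if tissue in config.planted_clade:
            offsets[tissue] = clade_shared + rng.normal(
                0.0, config.clade_member_noise_sd, size=n_genes
            )
        else:
            offsets[tissue] = rng.normal(0.0, config.tissue_effect_sd,
                                         size=n_genes)

    # expression-profile twins of the seed (same base, same offsets)
    seed_i = gene_index[config.seed_symbol]
    for g in seed_profile:
        i = gene_index[g]
        base[i] = base[seed_i] + rng.normal(0.0, config.seed_profile_base_sd)
        brain[i] = brain[seed_i] + rng.normal(0.0, config.seed_profile_noise_sd)
        clade_shared[i] = clade_shared[seed_i] + rng.normal(
            0.0, config.seed_profile_noise_sd
        )
        for tissue in tissues:
            if tissue not in config.planted_clade:
                offsets[tissue][i] = offsets[tissue][seed_i] + rng.normal(
                    0.0, config.seed_profile_noise_sd
                )
            else:
                offsets[tissue][i] = clade_shared[i] + rng.normal(
                    0.0, config.clade_member_noise_sd
                )

    # per-gene latent weights so every planted pair hits the target r
    # regardless of its base expression (count noise depends on the mean)
    coex_idx = [gene_index[g] for g in coex_set]
    base[coex_idx] = np.maximum(base[coex_idx], config.coex_base_floor)
    seed_base = float(base[seed_i])
    if coex_set:
        median_base = float(np.median(base[coex_idx]))
        w_seed = calibrate_latent_weight(
            config.coex_target_r, seed_base, median_base, config.nb_dispersion
        )
        gene_weights = {
            g: calibrate_latent_weight(
                config.coex_target_r, float(base[gene_index[g]]), seed_base,
                config.nb_dispersion, w_fixed=w_seed,
            )
            for g in coex_set
        }
    else:  # nothing planted: the latent factor is absent entirely
        w_seed = 0.0
        gene_weights = {}
    coex_rows = np.array(coex_idx + [seed_i])
    w_vec = np.array([gene_weights[g] for g in coex_set] + [w_seed])
    de_rows = np.array([gene_index[g] for g in de_genes], dtype=int)
    log_fold = math.log(config.de_fold)

    blocks = []
    sample_ids: list[str] = []
    sample_tissues: list[str] = []
    for tissue in tissues:
        n = config.samples_per_tissue
        log_mu = base[:, None] + offsets[tissue][:, None]
        if tissue in config.brain_tissues:
            log_mu = log_mu + brain[:, None]
        if tissue == config.de_tissue:
            log_mu[de_rows] += log_fold
        log_mu = np.broadcast_to(log_mu, (n_genes, n)).copy()
        if tissue in config.planted_clade:
            z = rng.normal(size=n)
            log_mu[coex_rows] += (
                w_vec[:, None] * z[None, :] - (w_vec**2 / 2)[:, None]
            )
        blocks.append(_nb_draw(rng, np.exp(log_mu), config.nb_dispersion))
        sample_ids.extend(f"{tissue}_s{j:03d}" for j in range(n))
        sample_tissues.extend([tissue] * n)

    counts = np.concatenate(blocks, axis=1)

    # high-missingness genes: excess zeros in one clade tissue
    zero_tissue = config.planted_clade[0]
    zero_cols = [
        j for j, t in enumerate(sample_tissues) if t == zero_tissue
    ]
    for g in high_missing:
        hit = rng.choice(zero_cols, size=max(2, len(zero_cols) // 10),
                         replace=False)
        counts[gene_index[g], hit] = 0

    frame = pd.DataFrame(counts, index=genes, columns=sample_ids)
    frame = frame.loc[keep_genes]

    a, b = config.mapping_rate_beta
    rates = rng.beta(a, b, size=len(sample_ids))
    low_rate = [str(s) for s in rng.choice(sample_ids, size=config.n_low_rate_samples, replace=False)]
    meta = pd.DataFrame(
        {"tissue": sample_tissues, "mapping_rate": rates}, index=sample_ids
    )
    meta.loc[low_rate, "mapping_rate"] = rng.uniform(
        0.5, 0.79, size=len(low_rate)
    )

    matrix = CountMatrix(frame, meta)
    truth = CountsTruth(
        planted_clade=list(config.planted_clade),
        coex_set=sorted(coex_set),
        coex_target_r=config.coex_target_r,
        latent_weight=w_seed,
        latent_weights={g: round(v, 4) for g, v in sorted(gene_weights.items())},
        de_genes=sorted(de_genes),
        de_tissue=config.de_tissue,
        de_fold=config.de_fold,
        seed_profile_set=sorted(seed_profile),
        low_rate_samples=sorted(low_rate),
        high_missing_genes=sorted(high_missing),
        absent_members=sorted(absent),
        analysed_members=sorted(analysed),
    )
    return CountsSimulation(matrix, truth)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


@dataclass
class AnnotationTruth(GroundTruthMixin):
    planted_term: str
    oversize_term: str
    tissue_boundary_term: str
    seedless_term: str
    electronic_term: str


@dataclass
class AnnotationSimulation:
    gmt_lines: list[str]
    truth: AnnotationTruth

    def write_gmt(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.gmt_lines) + "\n")


def simulate_annotations(config: SimulationConfig) -> AnnotationSimulation:
    """GMT collection with one planted enriched term and boundary terms.

    * ``TERM_PLANTED`` (size 100): the seed plus half the analysed
      interactome -> survives every filter.
    * ``TERM_OVERSIZE`` (size 1501): significant but beyond the general
      term-size ceiling of 1500.
    * ``TERM_SIZE81``: significant, passes the general ceiling, removed
      in tissue-specific mode (ceiling 80).
    * ``TERM_NOSEED``: significant but the seed is not a member.
    * ``TERM_IEA``: its seed/interactor memberships are tagged as
      electronic, so dropping electronic annotations deflates it.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 303]))
    universe = config.gene_symbols
    interactors = config.interactor_symbols
    seed = config.seed_symbol
    non_members = [g for g in universe if g not in set(interactors) and g != seed]

    def random_fill(k: int, exclude: set[str]) -> list[str]:
        pool = [g for g in non_members if g not in exclude]
        return list(rng.choice(pool, size=k, replace=False))

    overlap = list(
        rng.choice(interactors, size=config.planted_term_overlap, replace=False)
    )
    lines = []
    planted = [seed] + overlap + random_fill(99 - len(overlap), set(overlap))
    lines.append("TERM_PLANTED\tplanted enriched process\t" + "\t".join(planted))

    oversize = [seed] + interactors + random_fill(
        1500 - len(interactors), set(interactors)
    )
    lines.append("TERM_OVERSIZE\toversized general term\t" + "\t".join(oversize))

    size81 = [seed] + list(rng.choice(interactors, size=25, replace=False))
    size81 += random_fill(81 - len(size81), set(size81))
    lines.append("TERM_SIZE81\ttissue-mode boundary term\t" + "\t".join(size81))

    noseed = list(rng.choice(interactors, size=30, replace=False))
    noseed += random_fill(70, set(noseed))
    lines.append("TERM_NOSEED\tsignificant but seed-free\t" + "\t".join(noseed))

    iea_members = [f"{seed}|IEA"] + [
        f"{g}|IEA" for g in rng.choice(interactors, size=20, replace=False)
    ] + random_fill(40, set())
    lines.append("TERM_IEA\telectronically annotated term\t" + "\t".join(iea_members))

    for i in range(config.n_background_terms):
        size = int(rng.integers(20, 400))
        members = list(rng.choice(non_members, size=size, replace=False))
        lines.append(f"TERM_BG{i:03d}\tbackground term {i}\t" + "\t".join(members))

    truth = AnnotationTruth(
        planted_term="TERM_PLANTED",
        oversize_term="TERM_OVERSIZE",
        tissue_boundary_term="TERM_SIZE81",
        seedless_term="TERM_NOSEED",
        electronic_term="TERM_IEA",
    )
    return AnnotationSimulation(lines, truth)


# ---------------------------------------------------------------------------
# writing everything to disk
# ---------------------------------------------------------------------------


def write_all_inputs(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Materialize every pipeline input plus ground truth under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ppi = simulate_ppi_sources(config)
    for source, frame in ppi.evidence.items():
        path = outdir / f"evidence_{source}.tsv"
        frame.to_csv(path, sep="\t", index=False)
        paths[f"evidence_{source}"] = path
    ppi.id_mapping.to_csv(outdir / "id_mapping.tsv", sep="\t", index=False)
    paths["id_mapping"] = outdir / "id_mapping.tsv"
    method_frame = pd.DataFrame(
        sorted(ppi.method_dictionary.items()), columns=["method_code", "method_group"]
    )
    method_frame.to_csv(outdir / "method_groups.tsv", sep="\t", index=False)
    paths["method_dictionary"] = outdir / "method_groups.tsv"
    ppi.truth.to_json(outdir / "truth_ppi.json")

    sim = simulate_counts(config)
    sim.matrix.write_gct(outdir / "counts.gct")
    sim.matrix.write_sample_meta(outdir / "samples.tsv")
    paths["counts"] = outdir / "counts.gct"
    paths["sample_meta"] = outdir / "samples.tsv"
    sim.truth.to_json(outdir / "truth_counts.json")

    annotations = simulate_annotations(config)
    annotations.write_gmt(outdir / "gene_sets.gmt")
    paths["gmt"] = outdir / "gene_sets.gmt"
    annotations.truth.to_json(outdir / "truth_annotations.json")
    return paths
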