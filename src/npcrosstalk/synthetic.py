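"""Fully synthetic study generator.

Emulates the statistical structure the analysis assumes so every downstream
stage is testable without any external download:

- per-disease log2 expression cohorts with case/control groups split over
  multiple batches carrying additive per-gene shifts and multiplicative
  noise-scale factors (exactly the generative model the empirical-Bayes
  batch correction assumes);
- planted differentially expressed genes per disease with a shared
  (crosstalk) subset expressed in both;
- a neuropeptide panel occupying the last rows of each matrix, disjoint from
  the DE background, with no planted group effect, except that (a) selected
  panel genes are linearly coupled to crosstalk genes with group-specific
  slopes (the differential-coexpression signal) and (b) selected panel genes
  carry a case-group mean shift (the predictive signal for the lasso screen);
- an Erdős–Rényi PPI graph with no direct crosstalk–neuropeptide edges and
  planted crosstalk–bridge–neuropeptide paths;
- pathway gene sets, a configurable number of which mix both gene roles.

Every quantity is reproducible from the config seed; planted identities are
recorded in a :class:`TruthLedger`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .bundle import ExpressionBundle

# seed-stream keys (mixed with the config seed, one stream per concern)
_KEY_DESIGN = 101
_KEY_COHORT = 211
_KEY_GRAPH = 307
_KEY_PATHWAYS = 401


@dataclass(frozen=True)
class CohortConfig:
    """Per-disease cohort sizes."""

    n_case: int
    n_control: int
    n_batches: int = 2


@dataclass
class SyntheticConfig:
    """Generator knobs; defaults mirror the study conditions.

    ``n_genes`` is the total gene count including the neuropeptide panel
    (panel genes occupy the last ``n_neuropeptides`` rows).  Default cohort
    sizes are the study's: 30/33 whole-blood samples over two datasets for
    the depression cohort, 430/139 gingival-tissue samples over three for
    the periodontitis cohort.  The panel holds 102 neuropeptide genes, 35
    crosstalk genes are planted DE in both diseases, and 4 panel genes are
    predictive of case status in both cohorts.
    """

    seed: int = 0
    n_genes: int = 2000
    n_neuropeptides: int = 102
    diseases: dict[str, CohortConfig] = field(
        default_factory=lambda: {
            "MDD": CohortConfig(n_case=30, n_control=33, n_batches=2),
            "PD": CohortConfig(n_case=430, n_control=139, n_batches=3),
        }
    )
    # expression model (log2 units)
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    noise_sd: float = 1.0
    batch_shift_sd: float = 1.0
    batch_scale_sd: float = 0.1
    # planted differential expression; by default every planted DE gene is
    # shared between the diseases (the crosstalk set), so truth-ledger
    # recovery of the intersection is exact — the permissive |log2FC|>0
    # screening rule otherwise admits ~5% of one disease's unique DE genes
    # into the intersection by chance.  Disease-unique DE genes are planted
    # whenever n_de_up + n_de_down > n_crosstalk_planted.
    n_de_up: int = 22
    n_de_down: int = 13
    de_lfc: float = 2.0
    n_crosstalk_planted: int = 35
    # differential-coexpression couplings (crosstalk gene → panel gene)
    n_drl_pairs: int = 8
    drl_beta_case: float = 1.5
    drl_beta_control: float = -0.5
    drl_noise_sd: float = 0.5
    # predictive panel genes
    n_predictive_np: int = 4
    predictive_shift: float = 2.0  # in units of residual (noise) SD
    # PPI graph
    ppi_n_nodes: int = 400
    ppi_edge_prob: float = 0.01
    n_planted_bridges: int = 20
    # pathway sets
    n_pathways: int = 50
    pathway_size_min: int = 10
    pathway_size_max: int = 40
    n_mixed_sets: int = 5

    def __post_init__(self) -> None:
        counts = [
            self.n_genes, self.n_neuropeptides, self.n_de_up, self.n_de_down,
            self.n_crosstalk_planted, self.n_drl_pairs, self.n_predictive_np,
            self.ppi_n_nodes, self.n_planted_bridges, self.n_pathways, self.n_mixed_sets,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if self.n_neuropeptides > self.n_genes:
            raise ValueError("n_neuropeptides exceeds n_genes")
        if not (0.0 <= self.ppi_edge_prob <= 1.0):
            raise ValueError("edge_prob must lie in [0, 1]")
        n_de = self.n_de_up + self.n_de_down
        if self.n_crosstalk_planted > n_de:
            raise ValueError("n_crosstalk_planted exceeds planted DE genes per disease")
        if self.n_drl_pairs > self.n_neuropeptides * max(self.n_crosstalk_planted, 1):
            raise ValueError("n_drl_pairs exceeds available crosstalk × panel pairs")
        if self.n_drl_pairs + self.n_predictive_np > self.n_neuropeptides:
            raise ValueError("coupled + predictive panel genes exceed panel size")
        background = self.n_genes - self.n_neuropeptides
        diseases = len(self.diseases)
        if n_de * diseases - self.n_crosstalk_planted * (diseases - 1) > background:
            raise ValueError("not enough background genes for the planted DE sets")
        for name, cohort in self.diseases.items():
            if cohort.n_case + cohort.n_control < 4:
                raise ValueError(f"{name}: need ≥4 samples")

    @property
    def background_genes_count(self) -> int:
        return self.n_genes - self.n_neuropeptides


# ---------------------------------------------------------------------------
# truth ledger


@dataclass
class TruthLedger:
    """Planted ground truth: what the generator buried for tests to recover."""

    de_genes: dict[str, dict[str, int]] = field(default_factory=dict)  # disease → gene → ±1
    crosstalk: dict[str, int] = field(default_factory=dict)            # gene → ±1
    drl_pairs: list[dict] = field(default_factory=list)
    predictive_np: list[str] = field(default_factory=list)
    bridges: list[tuple[str, str, str]] = field(default_factory=list)
    mixed_pathways: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bridges"] = [list(t) for t in self.bridges]
        return d


# ---------------------------------------------------------------------------
# deterministic study design (shared across the generator ops)


def gene_names(config: SyntheticConfig) -> tuple[list[str], list[str]]:
    """(background genes, neuropeptide panel genes); panel is disjoint from
    the background by construction."""
    width = max(4, len(str(config.background_genes_count)))
    background = [f"G{i + 1:0{width}d}" for i in range(config.background_genes_count)]
    panel = [f"NP{i + 1:03d}" for i in range(config.n_neuropeptides)]
    return background, panel


@dataclass(frozen=True)
class PanelSpec:
    genes: tuple[str, ...]
    couplings: tuple[tuple[str, str, float, float], ...]  # (crosstalk, np, β_case, β_control)
    predictive: tuple[str, ...]


@dataclass(frozen=True)
class StudyDesign:
    de_signs: dict          # disease → {gene: ±1}
    crosstalk: dict         # gene → ±1
    panel: PanelSpec


def _study_design(config: SyntheticConfig) -> StudyDesign:
    rng = np.random.default_rng([config.seed, _KEY_DESIGN])
    background, panel = gene_names(config)
    pool = list(background)
    rng.shuffle(pool)

    n_de = config.n_de_up + config.n_de_down
    up_frac = config.n_de_up / n_de if n_de else 0.0
    n_ct_up = min(config.n_de_up, round(config.n_crosstalk_planted * up_frac))
    n_ct_down = config.n_crosstalk_planted - n_ct_up
    if n_ct_down > config.n_de_down:
        n_ct_down = config.n_de_down
        n_ct_up = config.n_crosstalk_planted - n_ct_down

    cursor = 0
    crosstalk_genes = pool[cursor : cursor + config.n_crosstalk_planted]
    cursor += config.n_crosstalk_planted
    crosstalk = {
        g: (1 if i < n_ct_up else -1) for i, g in enumerate(crosstalk_genes)
    }

    de_signs: dict[str, dict[str, int]] = {}
    for disease in sorted(config.diseases):
        signs = dict(crosstalk)
        extra_up = config.n_de_up - n_ct_up
        extra_down = config.n_de_down - n_ct_down
        uniques = pool[cursor : cursor + extra_up + extra_down]
        cursor += extra_up + extra_down
        for i, g in enumerate(uniques):
            signs[g] = 1 if i < extra_up else -1
        de_signs[disease] = signs

    coupled_np = panel[: config.n_drl_pairs]
    predictive = tuple(panel[config.n_drl_pairs : config.n_drl_pairs + config.n_predictive_np])
    couplings = []
    for i, np_gene in enumerate(coupled_np):
        partner = crosstalk_genes[i % len(crosstalk_genes)] if crosstalk_genes else None
        if partner is None:
            raise ValueError("cannot plant couplings without planted crosstalk genes")
        couplings.append((partner, np_gene, config.drl_beta_case, config.drl_beta_control))
    panel_spec = PanelSpec(genes=tuple(panel), couplings=tuple(couplings), predictive=predictive)
    return StudyDesign(de_signs=de_signs, crosstalk=crosstalk, panel=panel_spec)


# ---------------------------------------------------------------------------
# generator operations


def generate_neuropeptide_panel(
    config: SyntheticConfig, couplings=None
) -> PanelSpec:
    """Panel gene list plus coupled-pair spec.

    Panel genes carry no planted group effect.  ``couplings`` may override
    the planted (crosstalk gene, panel gene, β_case, β_control) tuples;
    coupling to a gene that is not a planted crosstalk gene is rejected.
    """
    design = _study_design(config)
    if couplings is None:
        return design.panel
    valid_crosstalk = set(design.crosstalk)
    panel_set = set(design.panel.genes)
    checked = []
    for partner, np_gene, b_case, b_ctrl in couplings:
        if partner not in valid_crosstalk:
            raise ValueError(f"coupling target {partner!r} is not a planted crosstalk gene")
        if np_gene not in panel_set:
            raise ValueError(f"{np_gene!r} is not a panel gene")
        checked.append((partner, np_gene, float(b_case), float(b_ctrl)))
    return PanelSpec(
        genes=design.panel.genes, couplings=tuple(checked), predictive=design.panel.predictive
    )


def _batch_assignment(cohort: CohortConfig, disease: str) -> tuple[list[str], list[str], list[str]]:
    """Sample ids, group labels and batch labels with batches balanced across
    groups (round-robin within each group)."""
    sample_ids, groups, batches = [], [], []
    for group, count in (("case", cohort.n_case), ("control", cohort.n_control)):
        for i in range(count):
            sample_ids.append(f"{disease}_{group}_{i + 1:03d}")
            groups.append(group)
            batches.append(f"{disease}_b{i % cohort.n_batches + 1}")
    return sample_ids, groups, batches


def generate_disease_cohort(
    config: SyntheticConfig, disease_label: str
) -> tuple[ExpressionBundle, TruthLedger]:
    """One disease cohort (log2 matrix + metadata) plus its ledger fragment.

    Matrix = gene baseline + group effect (planted DE genes in cases)
    + panel couplings/shifts + per-batch additive shift and multiplicative
    noise scale + Gaussian noise.  Bit-identical under a fixed config seed.
    """
    if disease_label not in config.diseases:
        raise KeyError(f"unknown disease {disease_label!r}")
    cohort = config.diseases[disease_label]
    sample_ids, groups, batches = _batch_assignment(cohort, disease_label)
    batch_counts = pd.Series(batches).value_counts()
    if (batch_counts < 2).any():
        small = dict(batch_counts[batch_counts < 2])
        raise ValueError(
            f"degenerate config for {disease_label}: batch(es) with <2 samples: {small}"
        )

    design = _study_design(config)
    background, panel = gene_names(config)
    all_genes = background + panel
    gene_index = {g: i for i, g in enumerate(all_genes)}
    n_genes, n_samples = len(all_genes), len(sample_ids)

    disease_idx = sorted(config.diseases).index(disease_label)
    rng = np.random.default_rng([config.seed, _KEY_COHORT, disease_idx])

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, n_genes)
    noise = config.noise_sd * rng.normal(size=(n_genes, n_samples))
    signal = np.tile(baseline[:, None], (1, n_samples))

    case_mask = np.array([g == "case" for g in groups])
    for gene, sign in design.de_signs[disease_label].items():
        signal[gene_index[gene], case_mask] += sign * config.de_lfc
    for np_gene in design.panel.predictive:
        signal[gene_index[np_gene], case_mask] += config.predictive_shift * config.noise_sd

    # group-specific linear couplings: the panel gene tracks the crosstalk
    # gene's within-group variation with slope β_case / β_control; x is
    # centered within each group so the coupling plants no group-mean effect
    # (the panel stays non-DE, as observed for the real panel)
    for partner, np_gene, b_case, b_ctrl in design.panel.couplings:
        x = signal[gene_index[partner]] + noise[gene_index[partner]]
        j = gene_index[np_gene]
        coupled_noise = config.drl_noise_sd * rng.normal(size=n_samples)
        y = np.full(n_samples, baseline[j])
        for mask, beta in ((case_mask, b_case), (~case_mask, b_ctrl)):
            y[mask] += beta * (x[mask] - x[mask].mean())
        signal[j] = y
        noise[j] = coupled_noise

    matrix = np.empty_like(signal)
    batch_arr = np.array(batches)
    for batch in sorted(set(batches)):
        mask = batch_arr == batch
        shift = rng.normal(0.0, config.batch_shift_sd, n_genes)
        scale = np.exp(rng.normal(0.0, config.batch_scale_sd, n_genes))
        matrix[:, mask] = signal[:, mask] + shift[:, None] + scale[:, None] * noise[:, mask]

    bundle = ExpressionBundle(
        matrix=pd.DataFrame(matrix, index=pd.Index(all_genes, name="gene"), columns=sample_ids),
        metadata=pd.DataFrame(
            {"group": groups, "batch": batches}, index=pd.Index(sample_ids, name="sample_id")
        ),
        disease=disease_label,
    )
    fragment = TruthLedger(
        de_genes={disease_label: dict(design.de_signs[disease_label])},
        crosstalk=dict(design.crosstalk),
        drl_pairs=[
            {"crosstalk": c, "neuropeptide": n, "beta_case": bc, "beta_control": bct}
            for c, n, bc, bct in design.panel.couplings
        ],
        predictive_np=list(design.panel.predictive),
    )
    return bundle, fragment


def generate_ppi_and_pathways(
    config: SyntheticConfig, roles: dict[str, str]
) -> tuple[nx.Graph, dict[str, list[str]], TruthLedger]:
    """Erdős–Rényi background PPI graph (no direct crosstalk–neuropeptide
    edges) with planted bridge triples, plus pathway gene sets of which
    exactly ``n_mixed_sets`` contain both roles.

    ``roles`` maps gene symbols to 'crosstalk' / 'neuropeptide'; all other
    graph nodes are 'other'.
    """
    background, panel = gene_names(config)
    known = set(background) | set(panel)
    for gene in roles:
        if gene not in known:
            raise ValueError(f"role assigned to unknown gene {gene!r}")
    crosstalk = sorted(g for g, r in roles.items() if r == "crosstalk")
    neuropep = sorted(g for g, r in roles.items() if r == "neuropeptide")

    rng = np.random.default_rng([config.seed, _KEY_GRAPH])
    others_pool = [g for g in background if g not in roles]
    n_other = max(0, config.ppi_n_nodes - len(crosstalk) - len(neuropep))
    if n_other > len(others_pool):
        raise ValueError("ppi_n_nodes exceeds available genes")
    others = list(rng.choice(others_pool, size=n_other, replace=False)) if n_other else []
    nodes = crosstalk + neuropep + sorted(others)

    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    node_arr = np.array(nodes)
    iu, ju = np.triu_indices(len(nodes), k=1)
    mask = rng.random(len(iu)) < config.ppi_edge_prob
    cset, nset = set(crosstalk), set(neuropep)
    for a, b in zip(node_arr[iu[mask]], node_arr[ju[mask]]):
        direct = (a in cset and b in nset) or (b in cset and a in nset)
        if not direct:
            graph.add_edge(str(a), str(b))

    bridges: list[tuple[str, str, str]] = []
    if config.n_planted_bridges:
        if not crosstalk or not neuropep:
            raise ValueError("cannot plant bridges without both gene roles")
        if config.n_planted_bridges > len(others):
            raise ValueError("not enough 'other' nodes for distinct planted bridges")
        bridge_nodes = list(rng.choice(sorted(others), size=config.n_planted_bridges, replace=False))
        for i, bridge in enumerate(bridge_nodes):
            c = crosstalk[int(rng.integers(len(crosstalk)))]
            n = neuropep[int(rng.integers(len(neuropep)))]
            graph.add_edge(c, str(bridge))
            graph.add_edge(str(bridge), n)
            bridges.append((c, str(bridge), n))
    bridges.sort()

    # pathway sets: the first n_mixed_sets mix both roles; the rest never
    # contain a panel gene so exactly n_mixed_sets qualify downstream
    prng = np.random.default_rng([config.seed, _KEY_PATHWAYS])
    pathways: dict[str, list[str]] = {}
    mixed_names = []
    non_panel = [g for g in background]
    for i in range(config.n_pathways):
        name = f"PW_{i + 1:03d}"
        size = int(prng.integers(config.pathway_size_min, config.pathway_size_max + 1))
        if i < config.n_mixed_sets:
            if not crosstalk or not neuropep:
                raise ValueError("mixed pathway sets require both gene roles")
            n_c = int(prng.integers(1, min(3, len(crosstalk)) + 1))
            n_n = int(prng.integers(1, min(3, len(neuropep)) + 1))
            members = list(prng.choice(crosstalk, size=n_c, replace=False))
            members += list(prng.choice(neuropep, size=n_n, replace=False))
            filler_pool = [g for g in non_panel if g not in members]
            n_fill = max(0, size - len(members))
            members += list(prng.choice(filler_pool, size=n_fill, replace=False))
            mixed_names.append(name)
        else:
            members = list(prng.choice(non_panel, size=min(size, len(non_panel)), replace=False))
        pathways[name] = sorted(str(m) for m in members)

    ledger = TruthLedger(bridges=bridges, mixed_pathways=mixed_names)
    return graph, pathways, ledger


# ---------------------------------------------------------------------------
# whole study


@dataclass
class SyntheticStudy:
    config: SyntheticConfig
    bundles: dict[str, ExpressionBundle]
    panel: PanelSpec
    graph: nx.Graph
    pathways: dict[str, list[str]]
    ledger: TruthLedger


def generate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Generate all study inputs and a merged truth ledger."""
    design = _study_design(config)
    ledger = TruthLedger(
        crosstalk=dict(design.crosstalk),
        drl_pairs=[
            {"crosstalk": c, "neuropeptide": n, "beta_case": bc, "beta_control": bct}
            for c, n, bc, bct in design.panel.couplings
        ],
        predictive_np=list(design.panel.predictive),
    )
    bundles = {}
    for disease in sorted(config.diseases):
        bundle, fragment = generate_disease_cohort(config, disease)
        bundles[disease] = bundle
        ledger.de_genes.update(fragment.de_genes)

    roles = {g: "crosstalk" for g in design.crosstalk}
    roles.update({g: "neuropeptide" for g in design.panel.genes})
    graph, pathways, graph_ledger = generate_ppi_and_pathways(config, roles)
    ledger.bridges = graph_ledger.bridges
    ledger.mixed_pathways = graph_ledger.mixed_pathways
    return SyntheticStudy(
        config=config, bundles=bundles, panel=design.panel, graph=graph,
        pathways=pathways, ledger=ledger,
    )


def verify_ledger(study: SyntheticStudy) -> None:
    """Every identifier in the ledger must resolve in the generated artifacts."""
    ledger = study.ledger
    for disease, signs in ledger.de_genes.items():
        genes = study.bundles[disease].matrix.index
        missing = [g for g in signs if g not in genes]
        if missing:
            raise AssertionError(f"{disease}: ledger DE genes missing from matrix: {missing[:5]}")
    for bundle in study.bundles.values():
        genes = set(bundle.matrix.index)
        for g in list(ledger.crosstalk) + ledger.predictive_np:
            if g not in genes:
                raise AssertionError(f"ledger gene {g} missing from {bundle.disease} matrix")
        for pair in ledger.drl_pairs:
            if pair["crosstalk"] not in genes or pair["neuropeptide"] not in genes:
                raise AssertionError(f"ledger DRL pair unresolved: {pair}")
    for c, b, n in ledger.bridges:
        if not (study.graph.has_edge(c, b) and study.graph.has_edge(b, n)):
            raise AssertionError(f"planted bridge edges missing: {(c, b, n)}")
    for name in ledger.mixed_pathways:
        if name not in study.pathways:
            raise AssertionError(f"mixed pathway {name} missing")
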