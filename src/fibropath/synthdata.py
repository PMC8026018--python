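"""Synthetic inputs with planted, recoverable truth.

Every downstream stage of the pipeline (differential expression, gene-map
construction, guided pathway walks, drug re-ranking, structural screening)
consumes files that in the original study came from public repositories and
web services.  This module fabricates all of them from a single integer
seed, together with a record of the signal that was planted — which genes
are differentially expressed, which pathways they concentrate in, and how
the drug library partitions structurally — so recovery can be asserted
exactly.

The generators are deterministic: the same seed yields byte-identical
tables.  They model the statistical shape of the real inputs (log-scale
intensities, negative-binomial counts with unequal library sizes,
functional gene-gene weights in (0, 1], bit-vector fingerprints) without
claiming to reproduce any real platform's artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_NETWORK_TYPES = ("co-expression", "physical", "pathways")
FAILED_STATUSES = ("Suspended", "Terminated", "Withdrawn")


@dataclass
class SyntheticTruth:
    """What was planted: the ground truth downstream stages must recover."""

    planted_de_genes: set[tuple[str, str, float]] = field(default_factory=set)
    planted_pathways: set[str] = field(default_factory=set)
    planted_drug_clusters: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def de_gene_ids(self) -> set[str]:
        return {g for g, _, _ in self.planted_de_genes}

    def to_dict(self) -> dict:
        return {
            "planted_de_genes": sorted(
                [list(t) for t in self.planted_de_genes]
            ),
            "planted_pathways": sorted(self.planted_pathways),
            "planted_drug_clusters": dict(
                sorted(self.planted_drug_clusters.items())
            ),
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(
            planted_de_genes={
                (g, direction, float(e))
                for g, direction, e in d.get("planted_de_genes", [])
            },
            planted_pathways=set(d.get("planted_pathways", [])),
            planted_drug_clusters={
                k: int(v) for k, v in d.get("planted_drug_clusters", {}).items()
            },
            seed=int(d.get("seed", 0)),
        )


@dataclass
class ExpressionDataset:
    """A genes × samples matrix with its group labels and platform kind."""

    values: pd.DataFrame
    groups: pd.Series  # sample -> {"case", "control"}
    platform: str  # "intensity" | "counts"


@dataclass
class DrugLibrary:
    """Drug records plus the per-experiment repurposing-score tables."""

    drugs: pd.DataFrame  # drug_id, fingerprint, descriptors, scores, targets
    cmap_scores: pd.DataFrame  # drug_id, experiment, score  (long)
    l1000_entries: pd.DataFrame  # experiment, drug_id
    failed: pd.DataFrame  # drug_id, disease, status, fingerprint


def _gene_names(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(1, n + 1)]


def generate_expression_dataset(
    n_genes: int = 1000,
    n_case: int = 10,
    n_control: int = 10,
    platform: str = "intensity",
    effect_size: float = 2.0,
    noise_sd: float = 0.25,
    frac_de: float = 0.05,
    seed: int = 0,
    de_genes: list[str] | None = None,
) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Simulate a case/control expression matrix with planted DE genes.

    Parameters
    ----------
    platform
        ``"intensity"`` gives approximately normal log2-scale values, the
        shape of a normalized microarray.  ``"counts"`` gives non-negative
        integers from a Poisson-gamma (negative binomial) model with
        per-sample library-size multipliers spread over a 4x range, so
        between-sample normalization actually matters.
    effect_size
        Planted shift in log2 units (cases relative to controls); the sign
        per gene is random and recorded in the truth.
    frac_de
        Fraction of genes planted as differentially expressed.  Ignored
        when an explicit ``de_genes`` list is supplied.
    de_genes
        Optional explicit list of gene ids to plant (must be a subset of
        the generated universe); used when the planted genes must coincide
        with pathway membership.
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    if n_case < 2 or n_control < 2:
        raise ValueError("each group needs at least 2 samples")
    if platform not in ("intensity", "counts"):
        raise ValueError(f"unknown platform {platform!r}")
    if not 0.0 <= frac_de <= 1.0:
        raise ValueError("frac_de must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    samples = [f"case_{i:03d}" for i in range(1, n_case + 1)] + [
        f"ctrl_{i:03d}" for i in range(1, n_control + 1)
    ]
    groups = pd.Series(
        ["case"] * n_case + ["control"] * n_control, index=samples, name="group"
    )
    groups.index.name = "sample"

    if de_genes is None:
        n_de = int(round(frac_de * n_genes))
        de_idx = rng.choice(n_genes, size=n_de, replace=False)
        de_genes = [genes[i] for i in sorted(de_idx)]
    else:
        missing = set(de_genes) - set(genes)
        if missing:
            raise ValueError(f"de_genes outside universe: {sorted(missing)[:5]}")
        de_genes = sorted(set(de_genes))

    directions = rng.choice(["over", "under"], size=len(de_genes))
    shift = pd.Series(0.0, index=genes)
    truth = SyntheticTruth(seed=seed)
    for g, d in zip(de_genes, directions):
        s = effect_size if d == "over" else -effect_size
        shift[g] = s
        truth.planted_de_genes.add((g, str(d), float(effect_size)))

    baseline = rng.uniform(4.0, 12.0, size=n_genes)  # log2 scale
    log2_means = np.tile(baseline[:, None], (1, len(samples)))
    case_cols = np.array([groups[s] == "case" for s in samples])
    log2_means[:, case_cols] += shift.to_numpy()[:, None]

    if platform == "intensity":
        values = log2_means + rng.normal(0.0, noise_sd, size=log2_means.shape)
        df = pd.DataFrame(values, index=genes, columns=samples)
    else:
        # Poisson-gamma counts; library multipliers log-uniform over 4x.
        lib = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=len(samples)))
        mu = 2.0 ** (log2_means - 4.0)  # map log2 baseline to mean counts
        dispersion = 0.1
        lam = rng.gamma(1.0 / dispersion, mu * dispersion * lib[None, :])
        df = pd.DataFrame(
            rng.poisson(lam).astype(np.int64), index=genes, columns=samples
        )
    df.index.name = "gene"

    return ExpressionDataset(df, groups, platform), truth


def generate_functional_records(
    genes: list[str],
    n_types: int = 3,
    density: float = 0.2,
    seed: int = 0,
    weight_range: tuple[float, float] = (0.05, 1.0),
) -> pd.DataFrame:
    """Emulate exported per-network-type gene-pair weights.

    Each unordered gene pair appears at most once per network type, with a
    weight in (0, 1].  ``density`` is the probability a given (pair, type)
    edge exists.
    """
    if not 0.0 < density <= 1.0:
        raise ValueError("density must lie in (0, 1]")
    if n_types < 1 or n_types > len(DEFAULT_NETWORK_TYPES):
        raise ValueError(
            f"n_types must be in [1, {len(DEFAULT_NETWORK_TYPES)}]"
        )
    lo, hi = weight_range
    if not (0.0 < lo <= hi <= 1.0):
        raise ValueError("weights must lie in (0, 1]")

    rng = np.random.default_rng(seed)
    types = DEFAULT_NETWORK_TYPES[:n_types]
    genes = sorted(set(genes))
    rows = []
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            for t in types:
                if rng.random() < density:
                    w = rng.uniform(lo, hi)
                    rows.append((a, b, t, round(float(w), 6)))
    return pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "network_type", "weight"]
    )


def generate_pathway_definitions(
    genes: list[str],
    n_pathways: int = 50,
    size_range: tuple[int, int] = (10, 30),
    overlap_factor: float = 0.4,
    seed: int = 0,
    pool_factor: float = 3.0,
) -> dict[str, set[str]]:
    """Fabricate pathway membership (GMT-style) with tunable overlap.

    Each pathway draws a disjoint core from the gene list; a fraction
    ``overlap_factor`` of its members is then re-drawn from a shared pool
    of ``pool_factor`` times the maximum pathway size, so pairs of
    pathways share genes and the shared-gene pathway network is connected
    but sparse at default settings (pathway-crosstalk graphs link a
    pathway to a modest subset of the others, not to nearly all of them).
    ``overlap_factor = 0`` yields pairwise-disjoint pathways.
    """
    lo, hi = size_range
    if lo < 2:
        raise ValueError("pathway size lower bound must be >= 2")
    if hi < lo:
        raise ValueError("size_range upper bound below lower bound")
    if not 0.0 <= overlap_factor < 1.0:
        raise ValueError("overlap_factor must lie in [0, 1)")
    if pool_factor <= 0:
        raise ValueError("pool_factor must be positive")

    rng = np.random.default_rng(seed)
    genes = sorted(set(genes))
    sizes = rng.integers(lo, hi + 1, size=n_pathways)
    cores = [int(round(s * (1 - overlap_factor))) for s in sizes]
    pool_size = max(int(round(hi * pool_factor)), 2) if overlap_factor > 0 else 0
    if sum(cores) + pool_size > len(genes):
        raise ValueError(
            "not enough genes for disjoint pathway cores at these settings"
        )

    order = rng.permutation(len(genes))
    shuffled = [genes[i] for i in order]
    pool = shuffled[:pool_size]
    cursor = pool_size
    pathways: dict[str, set[str]] = {}
    for p in range(n_pathways):
        name = f"pw{p + 1:03d}"
        core = shuffled[cursor : cursor + cores[p]]
        cursor += cores[p]
        n_shared = int(sizes[p]) - cores[p]
        shared: list[str] = []
        if n_shared > 0:
            idx = rng.choice(pool_size, size=min(n_shared, pool_size), replace=False)
            shared = [pool[i] for i in idx]
        members = set(core) | set(shared)
        while len(members) < 2:  # degenerate guard for tiny size ranges
            members.add(shuffled[cursor])
            cursor += 1
        pathways[name] = members
    return pathways


def _fp_to_string(bits: np.ndarray) -> str:
    return "".join("1" if b else "0" for b in bits)


def generate_drug_library(
    n_drugs: int = 60,
    fp_bits: int = 256,
    n_clusters: int = 3,
    n_failed: int = 8,
    seed: int = 0,
    gene_universe: list[str] | None = None,
    target_pool: list[str] | None = None,
    n_experiments: int = 2,
    bit_density: float = 0.3,
    flip_prob: float = 0.03,
) -> tuple[DrugLibrary, SyntheticTruth]:
    """Fabricate a drug library with planted structural clusters.

    Fingerprints are bit vectors built from ``n_clusters`` random templates
    with per-bit flip noise, so intra-cluster Tanimoto similarity is high
    (>= 0.7 in expectation at the defaults) and inter-cluster similarity is
    low (< 0.5).  Physicochemical descriptors are drawn from drug-like
    ranges, and connectivity scores per experiment span [-100, 100].

    One failed drug is planted as a near-duplicate of a candidate in the
    first cluster, so the structural screen has a true positive to find.
    ``target_pool`` biases gene-target draws (e.g. toward genes of planted
    pathways) for half of the drugs.
    """
    if fp_bits < 32:
        raise ValueError("fp_bits must be >= 32")
    if n_failed >= n_drugs:
        raise ValueError("n_failed must be smaller than n_drugs")
    if n_clusters < 1 or n_clusters > n_drugs:
        raise ValueError("inconsistent cluster count")

    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seed=seed)

    templates = rng.random((n_clusters, fp_bits)) < bit_density
    labels = np.sort(rng.integers(0, n_clusters, size=n_drugs))
    # guarantee every cluster non-empty
    labels[:n_clusters] = np.arange(n_clusters)
    labels = np.sort(labels)

    drug_ids = [f"d{i:04d}" for i in range(1, n_drugs + 1)]
    fps = []
    for i, did in enumerate(drug_ids):
        flips = rng.random(fp_bits) < flip_prob
        fp = templates[labels[i]] ^ flips
        fps.append(fp)
        truth.planted_drug_clusters[did] = int(labels[i])

    experiments = [f"exp{j}" for j in range(1, n_experiments + 1)]
    rows = []
    for i, did in enumerate(drug_ids):
        mw = rng.uniform(150, 650)
        clogp = rng.uniform(-2, 7)
        hbd = int(rng.integers(0, 8))
        hba = int(rng.integers(0, 13))
        rotb = int(rng.integers(0, 14))
        tpsa = rng.uniform(20, 180)
        func = rng.uniform(0, 1)
        affin = rng.uniform(0, 1)
        pool = (
            target_pool
            if (target_pool and i % 2 == 0)
            else (gene_universe or [])
        )
        targets: list[str] = []
        if pool:
            k = int(rng.integers(1, min(6, len(pool)) + 1))
            idx = rng.choice(len(pool), size=k, replace=False)
            targets = sorted(pool[j] for j in idx)
        rows.append(
            {
                "drug_id": did,
                "fingerprint": _fp_to_string(fps[i]),
                "MW": round(float(mw), 2),
                "cLogP": round(float(clogp), 3),
                "HBD": hbd,
                "HBA": hba,
                "RotB": rotb,
                "TPSA": round(float(tpsa), 2),
                "functional_association": round(float(func), 4),
                "binding_affinity": round(float(affin), 4),
                "targets": ";".join(targets),
            }
        )
    drugs = pd.DataFrame(rows)

    score_rows = []
    for exp in experiments:
        scores = rng.uniform(-100, 100, size=n_drugs)
        for did, s in zip(drug_ids, scores):
            score_rows.append(
                {"drug_id": did, "experiment": exp, "score": round(float(s), 2)}
            )
    cmap_scores = pd.DataFrame(score_rows)

    l1000_rows = []
    n_listed = min(50, n_drugs)
    for exp in experiments:
        idx = rng.choice(n_drugs, size=n_listed, replace=False)
        for j in sorted(idx):
            l1000_rows.append({"experiment": exp, "drug_id": drug_ids[j]})
    l1000 = pd.DataFrame(l1000_rows)

    failed_rows = []
    for i in range(n_failed):
        fid = f"f{i + 1:03d}"
        if i == 0:
            # near-duplicate of the first cluster's first candidate
            flips = rng.random(fp_bits) < 0.01
            fp = fps[0] ^ flips
        else:
            fp = rng.random(fp_bits) < bit_density
        failed_rows.append(
            {
                "drug_id": fid,
                "disease": "fibrosis",
                "status": FAILED_STATUSES[i % len(FAILED_STATUSES)],
                "fingerprint": _fp_to_string(fp),
            }
        )
    failed = pd.DataFrame(failed_rows)

    return DrugLibrary(drugs, cmap_scores, l1000, failed), truth


@dataclass
class SyntheticBundle:
    """A complete set of pipeline inputs for one simulated disease."""

    expression: ExpressionDataset
    pathways: dict[str, set[str]]
    functional_records: pd.DataFrame
    drug_library: DrugLibrary
    truth: SyntheticTruth


def generate_bundle(
    n_genes: int = 2000,
    n_pathways: int = 50,
    n_planted_pathways: int = 3,
    n_case: int = 10,
    n_control: int = 10,
    platform: str = "intensity",
    effect_size: float = 2.0,
    noise_sd: float = 0.25,
    overlap_factor: float = 0.4,
    n_drugs: int = 60,
    n_drug_clusters: int = 3,
    n_failed: int = 8,
    n_background_map_genes: int = 40,
    seed: int = 0,
) -> SyntheticBundle:
    """Generate one coherent disease scenario end to end.

    The planted differentially expressed genes are exactly the members of
    ``n_planted_pathways`` randomly chosen pathways, and the functional
    gene-gene records concentrate weight on those genes (dense, heavy edges
    among planted members; sparse, light edges over a random background set
    emulating incidental signature genes).  A gene map built from these
    records therefore guides the pathway walker toward the planted
    pathways, which is the recoverable truth of the scenario.
    """
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)

    pathways = generate_pathway_definitions(
        genes,
        n_pathways=n_pathways,
        size_range=(10, 30),
        overlap_factor=overlap_factor,
        seed=int(rng.integers(2**31)),
    )
    # plant among the non-hub half of the network: the scenario models
    # pathways highlighted through the gene map, as opposed to pathways
    # any walker reaches through sheer topological weight
    strength: dict[str, float] = {p: 0.0 for p in pathways}
    plist = sorted(pathways)
    for i, a in enumerate(plist):
        for b in plist[i + 1 :]:
            w = len(pathways[a] & pathways[b])
            strength[a] += w
            strength[b] += w
    ranked = sorted(plist, key=lambda p: (strength[p], p))
    low_half = ranked[: max(n_planted_pathways, len(ranked) // 2)]
    planted = sorted(
        low_half[i]
        for i in rng.choice(len(low_half), size=n_planted_pathways, replace=False)
    )
    # perturbed pathways of one disease cross-talk: give the planted set a
    # small shared gene clique so their mutual edges carry real weight and
    # guided walks route between them directly
    used = set().union(*pathways.values())
    spare = sorted(set(genes) - used)
    crosstalk = spare[: min(2, len(spare))]
    for p in planted:
        pathways[p] = pathways[p] | set(crosstalk)
    planted_members = sorted(set().union(*(pathways[p] for p in planted)))

    expr, truth = generate_expression_dataset(
        n_genes=n_genes,
        n_case=n_case,
        n_control=n_control,
        platform=platform,
        effect_size=effect_size,
        noise_sd=noise_sd,
        seed=int(rng.integers(2**31)),
        de_genes=planted_members,
    )
    truth.planted_pathways = set(planted)
    truth.seed = seed

    # the functional module driving the walker: genes exclusive to the
    # planted pathways (multi-pathway genes would diffuse the guidance
    # over every pathway they belong to, which is background behavior)
    n_memberships: dict[str, int] = {}
    for members in pathways.values():
        for g in members:
            n_memberships[g] = n_memberships.get(g, 0) + 1
    module_genes = sorted(
        g for g in planted_members if n_memberships[g] == 1
    )
    signal = generate_functional_records(
        module_genes,
        n_types=3,
        density=0.5,
        seed=int(rng.integers(2**31)),
        weight_range=(0.5, 1.0),
    )
    bg_pool = sorted(set(genes) - set(planted_members))
    bg_idx = rng.choice(len(bg_pool), size=n_background_map_genes, replace=False)
    background = generate_functional_records(
        [bg_pool[i] for i in sorted(bg_idx)],
        n_types=3,
        density=0.05,
        seed=int(rng.integers(2**31)),
        weight_range=(0.05, 0.3),
    )
    records = pd.concat([signal, background], ignore_index=True)

    drug_lib, drug_truth = generate_drug_library(
        n_drugs=n_drugs,
        n_clusters=n_drug_clusters,
        n_failed=n_failed,
        seed=int(rng.integers(2**31)),
        gene_universe=genes,
        target_pool=planted_members,
    )
    truth.planted_drug_clusters = drug_truth.planted_drug_clusters

    return SyntheticBundle(expr, pathways, records, drug_lib, truth)
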