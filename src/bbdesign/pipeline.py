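"""End-to-end experiment orchestration.

Each ``run_*`` function performs one of the package's standard analyses as
a pure function of its configuration (plus input catalogs), emits every
figure-producing number as a machine-readable table, and is deterministic
given the config seed.  The experiments:

* ``run_truncate_space_comparison`` — joint truncate similarity matrix and
  UMAP embedding across the three BB classes, with per-class density views
  and pairwise unique-truncate overlap counts;
* ``run_stratification``            — nested cost or MW threshold filters
  with retained counts and fractions per class;
* ``run_selection_comparison``      — random vs diversity vs uniform
  selection from one pool, with per-method nn-Tanimoto summaries;
* ``run_library_comparison``        — cost-tiered 192 x 192 random DEL2
  libraries: enumeration, product-PCP summaries, per-cycle nn-Tanimoto
  medians and total BB cost, with replicate sampling over seeds;
* ``compare_to_reference``          — intra- and cross-set nn-Tanimoto of
  enumerated products against a user-supplied reference collection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import BBClass, Catalog
from .errors import ConfigError, PoolExhaustedError
from .projection import EmbedParams, Embedding, density, embed, subset_view
from .selection import select_diverse, select_random, select_uniform
from .similarity import SimilarityMatrix, all_by_all, nn_tanimoto
from .synthetic_data import generate_paired_catalogs
from .truncate import class_filter, cost_filter, pcp_filter, truncate_catalog, unique_truncates
from .enumeration import LibraryDesign, enumerate_library, library_pcp_summary

__all__ = [
    "RunConfig",
    "ComparisonReport",
    "build_catalogs",
    "truncate_classes",
    "run_truncate_space_comparison",
    "run_stratification",
    "run_selection_comparison",
    "run_library_comparison",
    "compare_to_reference",
]

COST_TIERS = (100.0, 250.0, 500.0)  # USD per 250 mg
MW_TIERS = (200.0, 250.0, 300.0)  # Da


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    seed: int = 0
    outdir: Path | None = None
    # synthetic catalog sizes
    n_fmoc: int = 300
    n_amine: int = 1200
    n_acid: int = 800
    overlap_fraction: float = 0.6
    # analysis parameters
    cost_tiers: tuple[float, ...] = COST_TIERS
    mw_tiers: tuple[float, ...] = MW_TIERS
    library_mw_cutoff: float = 250.0
    k: int = 192
    embed_params: EmbedParams = field(default_factory=EmbedParams)
    uniform_threshold: float = 1.0
    n_replicates: int = 5
    make_plots: bool = False


@dataclass
class ComparisonReport:
    """Tables + scalar metrics from one experiment, ready to serialize."""

    name: str
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)

    def save(self, outdir: Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for key, df in self.tables.items():
            df.to_csv(outdir / f"{self.name}_{key}.csv", index=False)
        pd.Series(self.metrics, dtype=object).to_json(
            outdir / f"{self.name}_metrics.json"
        )


def build_catalogs(config: RunConfig) -> dict[BBClass, Catalog]:
    """Synthetic class catalogs for a run, deterministic in config.seed."""
    return generate_paired_catalogs(
        config.seed,
        n_fmoc=config.n_fmoc,
        n_amine=config.n_amine,
        n_acid=config.n_acid,
        overlap_fraction=config.overlap_fraction,
    )


def truncate_classes(catalogs: dict[BBClass, Catalog]):
    """Class-filter and truncate each catalog; returns per-class truncates."""
    out = {}
    for cls, cat in catalogs.items():
        kept, _ = class_filter(cat)
        truncs, _ = truncate_catalog(kept)
        out[cls] = truncs
    return out


def _joint_similarity(truncates: dict) -> tuple[SimilarityMatrix, dict[BBClass, list[str]]]:
    ids: list[str] = []
    smiles: list[str] = []
    per_class: dict[BBClass, list[str]] = {}
    for cls, truncs in truncates.items():
        per_class[cls] = [t.parent_id for t in truncs]
        ids.extend(t.parent_id for t in truncs)
        smiles.extend(t.smiles for t in truncs)
    return all_by_all(smiles, ids), per_class


def run_truncate_space_comparison(
    config: RunConfig, catalogs: dict[BBClass, Catalog] | None = None
) -> ComparisonReport:
    """Joint truncate-space analysis of the three BB classes."""
    catalogs = catalogs or build_catalogs(config)
    truncates = truncate_classes(catalogs)
    sim, per_class = _joint_similarity(truncates)
    embedding = embed(sim.to_distance(), config.embed_params)

    counts = pd.DataFrame(
        [
            {
                "bb_class": cls.value,
                "n_bbs": len(catalogs[cls]),
                "n_truncates": len(truncates[cls]),
                "n_unique_truncates": len(unique_truncates(truncates[cls])),
            }
            for cls in truncates
        ]
    )
    overlap_rows = []
    keys = {cls: set(unique_truncates(truncates[cls])) for cls in truncates}
    classes = list(keys)
    for i, a in enumerate(classes):
        for b in classes[i + 1 :]:
            overlap_rows.append(
                {
                    "class_a": a.value,
                    "class_b": b.value,
                    "shared": len(keys[a] & keys[b]),
                    "unique_a": len(keys[a] - keys[b]),
                    "unique_b": len(keys[b] - keys[a]),
                }
            )
    report = ComparisonReport(
        "truncate_space",
        tables={
            "counts": counts,
            "overlap": pd.DataFrame(overlap_rows),
            "embedding": embedding.to_frame().rename_axis("id").reset_index(),
        },
        metrics={"n_total_truncates": int(counts["n_truncates"].sum())},
    )
    if config.outdir:
        report.save(config.outdir)
        if config.make_plots:
            for cls in per_class:
                view = subset_view(embedding, per_class[cls])
                _plot_density(
                    view, Path(config.outdir) / f"truncate_space_{cls.value}.png"
                )
    return report


def run_stratification(
    config: RunConfig,
    axis: str,
    thresholds: tuple[float, ...] | None = None,
    catalogs: dict[BBClass, Catalog] | None = None,
) -> ComparisonReport:
    """Nested cost or MW stratification with retained-fraction tables."""
    if axis not in ("cost", "mw"):
        raise ConfigError(f"unknown stratification axis {axis!r}")
    thresholds = tuple(thresholds or (config.cost_tiers if axis == "cost" else config.mw_tiers))
    if list(thresholds) != sorted(thresholds):
        raise ConfigError("thresholds must be ascending")
    catalogs = catalogs or build_catalogs(config)

    rows = []
    tier_ids: dict[tuple[str, float], set[str]] = {}
    for cls, cat in catalogs.items():
        kept, _ = class_filter(cat)
        for thr in thresholds:
            if axis == "cost":
                filtered, _ = cost_filter(kept, thr)
            else:
                filtered, _ = pcp_filter(kept, thr)
            tier_ids[(cls.value, thr)] = set(filtered.ids())
            rows.append(
                {
                    "bb_class": cls.value,
                    "axis": axis,
                    "threshold": thr,
                    "n_in": len(kept),
                    "n_retained": len(filtered),
                    "retained_fraction": len(filtered) / len(kept) if len(kept) else 0.0,
                }
            )
    # monotone nesting across ascending thresholds, by construction
    for cls in catalogs:
        for lo, hi in zip(thresholds, thresholds[1:]):
            assert tier_ids[(cls.value, lo)] <= tier_ids[(cls.value, hi)]
    report = ComparisonReport(
        f"stratification_{axis}", tables={"retained": pd.DataFrame(rows)}
    )
    if config.outdir:
        report.save(config.outdir)
    return report


def run_selection_comparison(
    config: RunConfig,
    catalogs: dict[BBClass, Catalog] | None = None,
    bb_class: BBClass = BBClass.PRIMARY_AMINE,
) -> ComparisonReport:
    """Random vs diversity vs uniform selection from one filtered pool."""
    catalogs = catalogs or build_catalogs(config)
    pool_cat, _ = class_filter(catalogs[bb_class])
    truncs, _ = truncate_catalog(pool_cat)
    sim = all_by_all([t.smiles for t in truncs], [t.parent_id for t in truncs])
    embedding = embed(sim.to_distance(), config.embed_params)

    k = min(config.k, len(sim.ids))
    results = {
        "random": select_random(sim.ids, k, config.seed),
        "diversity": select_diverse(sim, k, config.seed),
        "uniform": select_uniform(
            embedding, k, config.uniform_threshold, config.seed
        ),
    }
    rows = []
    for name, res in results.items():
        _, median = nn_tanimoto(sim, res.chosen)
        rows.append(
            {
                "method": name,
                "k": k,
                "median_nn_tanimoto": median,
                "threshold": res.threshold,
            }
        )
    report = ComparisonReport(
        "selection_comparison",
        tables={
            "summary": pd.DataFrame(rows),
            "selections": pd.DataFrame(
                [
                    {"method": name, "rank": i, "id": bb_id}
                    for name, res in results.items()
                    for i, bb_id in enumerate(res.chosen)
                ]
            ),
        },
    )
    if config.outdir:
        report.save(config.outdir)
        if config.make_plots:
            _plot_selections(embedding, results, Path(config.outdir))
    return report


def run_library_comparison(
    config: RunConfig, catalogs: dict[BBClass, Catalog] | None = None
) -> ComparisonReport:
    """Cost-tiered random 192 x 192 DEL2 libraries, enumerated and compared."""
    catalogs = catalogs or build_catalogs(config)
    amines, _ = class_filter(catalogs[BBClass.PRIMARY_AMINE])
    acids, _ = class_filter(catalogs[BBClass.CARBOXYLIC_ACID])
    amines, _ = pcp_filter(amines, config.library_mw_cutoff)
    acids, _ = pcp_filter(acids, config.library_mw_cutoff)

    amine_sim = all_by_all(amines.smiles(), amines.ids())
    acid_sim = all_by_all(acids.smiles(), acids.ids())

    tier_rows, replicate_rows, pcp_tables = [], [], []
    for tier in config.cost_tiers:
        amine_pool, _ = cost_filter(amines, tier)
        acid_pool, _ = cost_filter(acids, tier)
        if len(amine_pool) < config.k or len(acid_pool) < config.k:
            tier_rows.append(
                {"cost_tier": tier, "status": "pool_exhausted",
                 "n_amines": len(amine_pool), "n_acids": len(acid_pool)}
            )
            continue
        pick_am = select_random(amine_pool.ids(), config.k, config.seed)
        pick_ac = select_random(acid_pool.ids(), config.k, config.seed + 1)
        design = LibraryDesign(
            "DEL2",
            [amine_pool.get(i) for i in pick_am.chosen],
            [acid_pool.get(i) for i in pick_ac.chosen],
        )
        products, enum_report = enumerate_library(design)
        summary = library_pcp_summary(products)
        # intralibrary diversity is judged on the intact BBs of each cycle
        _, nn_am = nn_tanimoto(amine_sim, pick_am.chosen)
        _, nn_ac = nn_tanimoto(acid_sim, pick_ac.chosen)
        cost_am = sum(amine_pool.get(i).cost for i in pick_am.chosen)
        cost_ac = sum(acid_pool.get(i).cost for i in pick_ac.chosen)
        tier_rows.append(
            {
                "cost_tier": tier,
                "status": "ok",
                "n_products": enum_report.n_products,
                "n_failures": len(enum_report.failures),
                "median_nn_tanimoto_amine": nn_am,
                "median_nn_tanimoto_acid": nn_ac,
                "total_cost_cycle1": cost_am,
                "total_cost_cycle2": cost_ac,
                "ro5_pass_fraction": summary["ro5_pass_fraction"],
                **{f"median_{k}": v for k, v in summary["medians"].items()},
            }
        )
        table = summary["table"].copy()
        table.insert(0, "cost_tier", tier)
        pcp_tables.append(table)
        for rep in range(config.n_replicates):
            seed = config.seed + 1000 + rep
            r_am = select_random(amine_pool.ids(), config.k, seed)
            r_ac = select_random(acid_pool.ids(), config.k, seed + 500)
            _, m_am = nn_tanimoto(amine_sim, r_am.chosen)
            _, m_ac = nn_tanimoto(acid_sim, r_ac.chosen)
            replicate_rows.append(
                {"cost_tier": tier, "replicate": rep,
                 "median_nn_tanimoto_amine": m_am, "median_nn_tanimoto_acid": m_ac}
            )
    report = ComparisonReport(
        "library_comparison",
        tables={
            "tiers": pd.DataFrame(tier_rows),
            "replicates": pd.DataFrame(replicate_rows),
            "products": pd.concat(pcp_tables, ignore_index=True)
            if pcp_tables
            else pd.DataFrame(),
        },
    )
    if config.outdir:
        report.save(config.outdir)
        if config.make_plots and pcp_tables:
            _plot_pcp_densities(report.tables["products"], Path(config.outdir))
    return report


def compare_to_reference(
    product_smiles: list[str],
    reference_smiles: list[str],
    sample_fraction: float = 1.0,
    seed: int = 0,
) -> ComparisonReport:
    """Intra- and cross-set nn-Tanimoto of products vs a reference set.

    The reference is user-supplied (e.g. a lead-like screening collection);
    ``sample_fraction`` subsamples the reference proportionally.
    """
    if not reference_smiles:
        raise ValueError("reference set is empty")
    if not product_smiles:
        raise ValueError("product set is empty")
    rng = np.random.default_rng(seed)
    if sample_fraction < 1.0:
        n_keep = max(2, int(round(sample_fraction * len(reference_smiles))))
        idx = rng.choice(len(reference_smiles), n_keep, replace=False)
        reference_smiles = [reference_smiles[i] for i in sorted(idx)]
    prod_ids = [f"prod_{i}" for i in range(len(product_smiles))]
    ref_ids = [f"ref_{i}" for i in range(len(reference_smiles))]
    joint = all_by_all(product_smiles + reference_smiles, prod_ids + ref_ids)
    n_p = len(prod_ids)
    cross_block = joint.values[:n_p, n_p:]

    _, intra_prod = nn_tanimoto(joint, prod_ids)
    if len(ref_ids) >= 2:
        _, intra_ref = nn_tanimoto(joint, ref_ids)
    else:
        intra_ref = float("nan")
    cross = cross_block.max(axis=1)  # per product: best match in reference
    metrics = {
        "median_intra_product_nn": intra_prod,
        "median_intra_reference_nn": intra_ref,
        "median_cross_nn": float(np.median(cross)),
        "n_products": n_p,
        "n_reference": len(ref_ids),
    }
    return ComparisonReport(
        "reference_comparison",
        tables={
            "cross_nn": pd.DataFrame({"id": prod_ids, "cross_nn_tanimoto": cross})
        },
        metrics=metrics,
    )


# -- plotting (headless) ----------------------------------------------------


def _plot_density(view: Embedding, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    surf = density(view)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.pcolormesh(surf.x, surf.y, surf.values, cmap="Greys", shading="auto")
    ax.scatter(view.coords[:, 0], view.coords[:, 1], s=2, c="k", alpha=0.3)
    ax.set_xlabel("UMAP-1")
    ax.set_ylabel("UMAP-2")
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _plot_selections(embedding: Embedding, results: dict, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    surf = density(embedding)
    for name, res in results.items():
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.pcolormesh(surf.x, surf.y, surf.values, cmap="Greys", shading="auto")
        view = subset_view(embedding, res.chosen)
        ax.scatter(view.coords[:, 0], view.coords[:, 1], s=6, c="tab:red")
        ax.set_title(name)
        fig.savefig(outdir / f"selection_{name}.png", dpi=150)
        plt.close(fig)


def _plot_pcp_densities(products: pd.DataFrame, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .enumeration import RO5_THRESHOLDS

    props = ["mw", "clogp", "tpsa", "hbd"]
    fig, axes = plt.subplots(1, 4, figsize=(16, 3.5))
    for ax, prop in zip(axes, props):
        for tier, grp in products.groupby("cost_tier"):
            grp[prop].plot.kde(ax=ax, label=f"<=${tier:g}")
        thr = RO5_THRESHOLDS.get(prop)
        if thr is not None:
            ax.axvline(thr, ls="--", c="k")
        ax.set_xlabel(prop)
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(outdir / "library_pcp_densities.png", dpi=150)
    plt.close(fig)
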