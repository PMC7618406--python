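"""End-to-end dress rehearsal of the full analysis pipeline.

:func:`run_rehearsal` exercises every stage on synthetic data with known
ground truth: corpus generation, vocabulary extraction, cooccurrence and
embedding training for three corpus variants (math, a structurally
degraded "non-math" control and their concatenation), stratified pair
selection, simulated familiarity and similarity ratings, the full
behavioral analysis battery, IRT, and the geometry probes.  It writes
figure files (familiarity-by-education curves, the binned
similarity-versus-cosine curve, dimensionality and group breakdowns, the
cluster map) plus TSV tables and a JSON report of headline quantities.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .cooccurrence import build_cooccurrence
from .corpus import GRADE_GROUPS, build_vocabulary
from .geometry import axis_project, domain_contrast, pca_project, semantic_map
from .glove import train_constrained, train_glove
from .irt import (
    curate_items,
    dichotomize,
    fit_2pl,
    irt_descriptive_concordance,
    select_discriminative_subset,
)
from .similarity import (
    aggregate_ratings,
    category_contrast,
    compare_models_aic,
    cosine,
    euclidean,
    fit_by_group,
    fit_rank_glm,
    noise_ceiling,
    percentile_bin,
    select_pairs,
    spearman,
)
from .synthetic import (
    BehaviorSpec,
    WorldSpec,
    generate_corpus,
    generate_familiarity,
    generate_participants,
    generate_similarity,
    make_item_bank,
)

__all__ = ["run_rehearsal"]

REHEARSAL_DIMS = (1, 2, 5, 10, 25, 50)


def _pair_frame(pairs) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "word_a": [p.word_a for p in pairs],
            "word_b": [p.word_b for p in pairs],
            "grade_group": [p.grade_group for p in pairs],
            "category": [p.category for p in pairs],
            "true_cosine": [p.predicted_cosine for p in pairs],
        }
    )


def run_rehearsal(
    outdir: str | Path,
    seed: int = 0,
    n_participants: int = 400,
    dims: tuple[int, ...] = REHEARSAL_DIMS,
    world: WorldSpec | None = None,
    make_figures: bool = True,
) -> dict:
    """Run the full pipeline on synthetic data; return the report dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": seed}

    # --- world and corpora -------------------------------------------------
    world = world or WorldSpec(seed=seed)
    corpus, truth = generate_corpus(world)
    # control corpus: same vocabulary, topical structure mostly washed out
    alt_world = replace(world, topic_mixing=0.9, seed=world.seed + 1)
    alt_corpus, _ = generate_corpus(alt_world)

    vocab_entries = build_vocabulary(corpus, max_size=50_000, min_count=5)
    words = [e.word for e in vocab_entries]
    logfreq = {e.word: e.logfreq_math for e in vocab_entries}
    report["vocabulary_size"] = len(words)

    X_math = build_cooccurrence(corpus, words, window=15)
    X_non = build_cooccurrence(alt_corpus, words, window=15)

    emb_math = train_glove(X_math, dim=25, seed=seed, corpus_variant="math")
    emb_non = train_constrained(
        X_non, words, dim=25, seed=seed + 1, corpus_variant="nonmath"
    )
    # the "global" corpus variant mixes both corpora's evidence
    both = build_cooccurrence(
        type(corpus)(corpus.documents + alt_corpus.documents, "global"), words, window=15
    )
    emb_glob = train_constrained(
        both, words, dim=25, seed=seed + 2, corpus_variant="global"
    )
    embeddings = {"math": emb_math, "nonmath": emb_non, "global": emb_glob}

    # planted-structure check on the math embedding
    topics = {}
    for w in words:
        if w in truth.topic_of and not (w.startswith("shapectx")):
            topics.setdefault(truth.topic_of[w], []).append(w)
    intra, inter = [], []
    tlist = sorted(topics)
    for ti in tlist:
        Vi = emb_math.subset(topics[ti])
        Ui = Vi / np.linalg.norm(Vi, axis=1, keepdims=True)
        C = Ui @ Ui.T
        intra.extend(C[np.triu_indices(len(topics[ti]), k=1)].tolist())
        for tj in tlist:
            if tj > ti:
                Vj = emb_math.subset(topics[tj])
                Uj = Vj / np.linalg.norm(Vj, axis=1, keepdims=True)
                inter.extend((Ui @ Uj.T).ravel().tolist())
    report["topic_separation"] = float(np.mean(intra) - np.mean(inter))

    # --- pair selection and simulated behavior -----------------------------
    # grade groups cut across topics so each group spans the whole cosine
    # range (from same-topic to cross-topic pairs)
    group_of = {}
    counter = 0
    for w in words:
        if w in truth.log_magnitude or w.startswith(("shape", "shapectx")):
            group_of[w] = "primary"
        else:
            group_of[w] = GRADE_GROUPS[counter % len(GRADE_GROUPS)]
            counter += 1
    word_groups = pd.DataFrame({"word": words, "grade_group": [group_of[w] for w in words]})
    pairs = select_pairs(emb_math, word_groups, k_per_category=3)
    pairs_df = _pair_frame(pairs)
    # low-ability raters track the degraded-corpus similarity instead
    alt = []
    for wa, wb in zip(pairs_df["word_a"], pairs_df["word_b"]):
        if wa in emb_non and wb in emb_non:
            alt.append(cosine(emb_non.vector(wa), emb_non.vector(wb)))
        else:
            alt.append(0.0)
    pairs_df["alt_cosine"] = alt
    report["n_pairs"] = len(pairs_df)

    behavior = BehaviorSpec(n_participants=n_participants, seed=seed + 10)
    participants, _theta = generate_participants(behavior)
    trials = generate_similarity(
        participants,
        pairs_df,
        gamma=behavior.gamma,
        noise_sd=0.6,
        attention=0.3,
        tracking=0.25,
        floor=0.15,
        seed=seed + 11,
    )
    grade_rank = {g: i for i, g in enumerate(GRADE_GROUPS)}
    items = make_item_bank(
        words,
        seed=seed + 12,
        grades={w: grade_rank[group_of[w]] for w in words},
        logfreqs=logfreq,
    )
    familiarity = generate_familiarity(
        participants, items, n_words=behavior.n_familiarity_words, seed=seed + 13
    )

    # --- similarity analyses ----------------------------------------------
    agg = aggregate_ratings(trials)
    cos_pred, euc_pred, mean_rating = [], [], []
    for (wa, wb), mr in agg["mean_rating"].items():
        cos_pred.append(cosine(emb_math.vector(wa), emb_math.vector(wb)))
        euc_pred.append(euclidean(emb_math.vector(wa), emb_math.vector(wb)))
        mean_rating.append(mr)
    res_cos = spearman(mean_rating, cos_pred)
    res_euc = spearman(mean_rating, euc_pred)
    report["spearman_cosine"] = res_cos.r_s
    report["spearman_euclidean"] = res_euc.r_s
    fit_cos = fit_rank_glm(
        pd.DataFrame({"rating": mean_rating, "pred": cos_pred}),
        "rating",
        ["pred"],
        interactions=False,
    )
    fit_euc = fit_rank_glm(
        pd.DataFrame({"rating": mean_rating, "pred": euc_pred}),
        "rating",
        ["pred"],
        interactions=False,
    )
    comp = compare_models_aic({"cosine": fit_cos, "euclidean": fit_euc})
    report["preferred_predictor"] = comp.preferred
    report["delta_aic_euclidean"] = comp.delta_aic["euclidean"]

    n_bins = max(5, min(50, len(mean_rating) // 10))
    xb, yb = percentile_bin(cos_pred, mean_rating, n_bins=n_bins)
    # convexity of the binned curve over the rising region (cosine > 0):
    # positive quadratic coefficient of y on x
    pos = xb > 0
    quad = np.polyfit(xb[pos], yb[pos], 2)[0]
    report["binned_curve_quadratic_coefficient"] = float(quad)

    contrast = category_contrast(trials)
    report["category_means"] = contrast["means"]
    report["kruskal_H"] = contrast["H"]
    report["kruskal_p"] = contrast["p"]

    ceiling = noise_ceiling(trials)
    report["noise_ceiling"] = ceiling
    single_trial = spearman(
        trials["rating"].to_numpy(),
        [cosine(emb_math.vector(a), emb_math.vector(b)) for a, b in zip(trials["word_a"], trials["word_b"])],
    )
    report["single_trial_r_squared"] = single_trial.r_squared
    report["fraction_of_ceiling"] = single_trial.r_squared / ceiling

    by_grade, trend_grade = fit_by_group(trials, embeddings, grouping="grade_group")
    by_edu, trend_edu = fit_by_group(
        trials, embeddings, grouping="education", participants=participants
    )
    report["education_trend_math"] = trend_edu.get("math", float("nan"))
    piv = by_edu.pivot(index="group", columns="variant", values="r_s")
    if {"math", "nonmath"} <= set(piv.columns):
        report["math_minus_nonmath_mean_r"] = float((piv["math"] - piv["nonmath"]).mean())

    # --- familiarity: rank GLM and IRT -------------------------------------
    fam = familiarity.merge(
        participants[["participant_id", "education_rank"]], on="participant_id"
    )
    fam["grade"] = fam["word"].map(lambda w: grade_rank[group_of[w]])
    fam["logfreq"] = fam["word"].map(logfreq)
    glm = fit_rank_glm(fam, "rating", ["education_rank", "grade", "logfreq"])
    report["glm_r_squared"] = glm.r_squared
    report["glm_beta_education"] = glm.coefficients["education_rank"][0]
    report["glm_beta_grade"] = glm.coefficients["grade"][0]
    report["glm_beta_logfreq"] = glm.coefficients["logfreq"][0]

    responses = dichotomize(familiarity)
    irt_fit = fit_2pl(responses, seed=seed)
    curated = curate_items(irt_fit)
    subset = select_discriminative_subset(curated, n=min(80, len(curated)))
    report["irt_n_items_fit"] = len(irt_fit.items)
    report["irt_n_excluded_degenerate"] = len(irt_fit.excluded_items)
    report["irt_n_curated"] = len(curated)
    report["irt_n_subset"] = len(subset)
    fam_means = familiarity.groupby("word")["rating"].mean().to_dict()
    edu_of = participants.set_index("participant_id")["education_rank"].to_dict()
    conc = irt_descriptive_concordance(
        irt_fit,
        fam_means,
        {w: grade_rank[group_of[w]] for w in words},
        logfreq,
        edu_of,
    )
    report["irt_r_difficulty_familiarity"] = conc["difficulty_vs_familiarity"].r_s
    report["irt_r_difficulty_grade"] = conc["difficulty_vs_grade"].r_s
    report["irt_r_ability_education"] = conc["ability_vs_education"].r_s

    # --- dimensionality sweep ----------------------------------------------
    dim_rs = {}
    for k, dim in enumerate(dims):
        emb_d = train_glove(X_math, dim=dim, seed=seed + 100 + k)
        preds = [
            cosine(emb_d.vector(a), emb_d.vector(b))
            for (a, b) in agg["mean_rating"].index
        ]
        try:
            dim_rs[dim] = spearman(mean_rating, preds).r_s
        except ValueError:  # e.g. 1-d cosines collapse to a single sign
            dim_rs[dim] = float("nan")
    report["r_s_by_dimension"] = {str(d): r for d, r in dim_rs.items()}

    # --- geometry -----------------------------------------------------------
    num_words = [w for w in words if w in truth.log_magnitude]
    if len(num_words) >= 3:
        _, coords, _ = pca_project(emb_math, num_words, n_components=2)
        logm = np.array([truth.log_magnitude[w] for w in num_words])
        r_pc1 = float(np.corrcoef(coords[:, 0], logm)[0, 1])
        report["numberline_pc1_r"] = abs(r_pc1)
        proj = axis_project(emb_math, num_words[0], num_words[-1], num_words[1:-1])
        tvals = [proj.coordinates[w] for w in num_words]
        report["numberline_axis_spearman"] = abs(spearman(tvals, logm).r_s)
    t0, t1 = sorted(topics)[:2]
    dc = domain_contrast(
        emb_math,
        {w: "d0" for w in topics[t0][:8]} | {w: "d1" for w in topics[t1][:8]},
        ("d0", "d1"),
    )
    report["domain_contrast_t"] = dc["t"]
    report["domain_contrast_df"] = dc["df"]

    smap = semantic_map(emb_math, words, k_range=(2, 10), seed=seed)
    report["map_k"] = smap.k

    # --- outputs ------------------------------------------------------------
    pairs_df.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
    trials.to_csv(outdir / "similarity_trials.tsv", sep="\t", index=False)
    familiarity.to_csv(outdir / "familiarity_trials.tsv", sep="\t", index=False)
    participants.to_csv(outdir / "participants.tsv", sep="\t", index=False)
    by_grade.to_csv(outdir / "fit_by_grade.tsv", sep="\t", index=False)
    by_edu.to_csv(outdir / "fit_by_education.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"word": smap.words, "cluster": smap.cluster_id, "x": smap.coords2d[:, 0], "y": smap.coords2d[:, 1]}
    ).to_csv(outdir / "semantic_map.tsv", sep="\t", index=False)

    if make_figures:
        _figures(outdir, fam, grade_rank, xb, yb, dim_rs, ceiling, by_edu, smap)

    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
    return report


def _figures(outdir, fam, grade_rank, xb, yb, dim_rs, ceiling, by_edu, smap):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # familiarity by education, one curve per word grade group
        fig, ax = plt.subplots(figsize=(6, 4))
        for g, sub in fam.groupby("grade"):
            curve = sub.groupby("education_rank")["rating"].mean()
            ax.plot(curve.index, curve.values, marker="o", label=f"grade group {g}")
        ax.set_xlabel("participant education rank")
        ax.set_ylabel("mean familiarity (0-8)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(outdir / "familiarity_by_education.png", dpi=120)
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(xb, yb, "o-", ms=3)
        ax.set_xlabel("embedding cosine similarity (binned)")
        ax.set_ylabel("mean similarity rating (0-5)")
        fig.tight_layout()
        fig.savefig(outdir / "similarity_curve.png", dpi=120)
        plt.close(fig)

        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        dimv = sorted(dim_rs)
        axes[0].plot(dimv, [dim_rs[d] ** 2 * 100 for d in dimv], "o-")
        axes[0].axhline(ceiling * 100, ls="--", color="gray", label="noise ceiling")
        axes[0].set_xlabel("embedding dimensionality")
        axes[0].set_ylabel("% variance (rank $r_s^2$)")
        axes[0].legend(fontsize=7)
        for variant, sub in by_edu.groupby("variant"):
            axes[1].plot(sub["group"], sub["r_s"], marker="o", label=variant)
        axes[1].set_xlabel("participant education")
        axes[1].set_ylabel("$r_s$")
        axes[1].tick_params(axis="x", rotation=60, labelsize=6)
        axes[1].legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(outdir / "fit_breakdowns.png", dpi=120)
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(smap.coords2d[:, 0], smap.coords2d[:, 1], c=smap.cluster_id, s=8, cmap="tab20")
        ax.scatter(smap.centers2d[:, 0], smap.centers2d[:, 1], c="black", marker="x")
        ax.set_title(f"semantic map (k={smap.k})")
        fig.tight_layout()
        fig.savefig(outdir / "semantic_map.png", dpi=120)
        plt.close(fig)
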