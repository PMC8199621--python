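"""Three-way CTC/cPSC classification against cultured reference cells.

Human cells recovered from the xenograft can only be one of the two
implanted types: AsPC-1 pancreatic cancer cells or pancreatic stellate
cells (PSCs).  Human cells in the blood compartment are therefore either
circulating tumour cells (CTCs) or circulating PSCs (cPSCs).  Three
complementary classifiers assign each blood cell a type:

* **Approach 1** — anchor-based integration of all samples with the
  cultured reference (Cult), then a k-nearest-neighbour vote in the joint
  2-D embedding against the labelled Cult cells.
* **Approach 2** — community clustering of the integrated population; each
  cluster inherits the majority type of its Cult members.
* **Approach 3** — no integration: a discriminative reference signature
  (top-N genes per cultured type) is built from Cult alone, blood cells are
  restricted to the signature genes and split by 2-group clustering.

The consensus call requires unanimity among available approach labels with
at least two approaches reporting.  A Fisher exact test contrasts
luciferase-transgene detection in putative cPSCs against all cancer cells:
the transgene is carried only by the implanted cancer line, so its
non-detection in cPSCs argues against a cancer identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .io_formats import CountMatrix
from .preprocess import (EmbeddingResult, build_knn, cluster_graph, embed_2d,
                         normalize_log, run_pca, select_hvg)

DEFAULT_N_TOP = 500


@dataclass
class ReferenceSignature:
    """Ordered discriminative gene lists for the two cultured cell types."""

    cancer_genes: list[str]
    psc_genes: list[str]
    scores: pd.DataFrame  # gene_id, z, p, lfc, direction

    def __post_init__(self) -> None:
        if set(self.cancer_genes) & set(self.psc_genes):
            raise ValueError("signature gene lists must be disjoint")


def _rank_sum(x_a: np.ndarray, x_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised two-sided Wilcoxon rank-sum per gene (rows).

    Normal approximation with tie correction and continuity correction;
    exact enumeration via scipy when either group has a single member.
    Returns (z, p); z > 0 means higher in group A.
    """
    n_a, n_b = x_a.shape[1], x_b.shape[1]
    n = n_a + n_b
    if min(n_a, n_b) == 0:
        raise ValueError("both groups must be non-empty")
    if min(n_a, n_b) == 1:
        warnings.warn("group of size 1: using exact rank distribution")
        z = np.zeros(x_a.shape[0])
        p = np.ones(x_a.shape[0])
        for i in range(x_a.shape[0]):
            res = scipy.stats.mannwhitneyu(
                x_a[i], x_b[i], alternative="two-sided", method="exact")
            u = res.statistic
            mu = n_a * n_b / 2
            z[i] = np.sign(u - mu)
            p[i] = res.pvalue
        return z, p

    pooled = np.concatenate([x_a, x_b], axis=1)
    ranks = scipy.stats.rankdata(pooled, axis=1)
    r_a = ranks[:, :n_a].sum(axis=1)
    u = r_a - n_a * (n_a + 1) / 2
    mu = n_a * n_b / 2
    # tie correction
    tie_term = np.zeros(pooled.shape[0])
    for i in range(pooled.shape[0]):
        _, counts = np.unique(pooled[i], return_counts=True)
        tie_term[i] = np.sum(counts ** 3 - counts)
    var = n_a * n_b / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    var[var <= 0] = np.nan
    z = (u - mu - np.sign(u - mu) * 0.5) / np.sqrt(var)
    z = np.nan_to_num(z)
    p = 2 * scipy.stats.norm.sf(np.abs(z))
    return z, np.clip(p, 0, 1)


# ---------------------------------------------------------------------------
# Integration (Approaches 1 & 2)


def _mnn_pairs(ref: np.ndarray, query: np.ndarray, k: int) -> list[tuple[int, int]]:
    """Mutual-nearest-neighbour (ref_idx, query_idx) pairs in a shared space."""
    from sklearn.neighbors import NearestNeighbors

    k_rq = min(k, ref.shape[0])
    k_qr = min(k, query.shape[0])
    nn_ref = NearestNeighbors(n_neighbors=k_rq).fit(ref)
    nn_query = NearestNeighbors(n_neighbors=k_qr).fit(query)
    _, q2r = nn_ref.kneighbors(query)     # for each query, nearest refs
    _, r2q = nn_query.kneighbors(ref)     # for each ref, nearest queries
    ref_sets = [set(row) for row in r2q]
    pairs = []
    for qi, refs in enumerate(q2r):
        for ri in refs:
            if qi in ref_sets[ri]:
                pairs.append((int(ri), qi))
    return pairs


def integrate_and_embed(
    samples: list[CountMatrix],
    seed: int = 0,
    n_hvg: int = 2000,
    k_pcs: int = 30,
    k_anchor: int = 10,
    reference_label: str = "Cult",
    compute_umap: bool = True,
) -> dict:
    """Anchor-correct samples toward the cultured reference and jointly embed.

    All samples are pooled on the shared gene axis, log-normalised, reduced
    to ``k_pcs`` principal components, and each non-reference sample is
    shifted by distance-weighted averages of the displacement vectors of its
    mutual-nearest-neighbour anchor pairs with the reference.  A single
    sample passes through uncorrected.

    Returns a dict with ``embedding`` (:class:`EmbeddingResult` over pooled
    cells), ``barcodes``, ``sample_of_cell`` and a per-sample ``report``.
    """
    if not samples:
        raise ValueError("no samples given")
    gene_ids = samples[0].genes.gene_id
    for s in samples[1:]:
        if not np.array_equal(s.genes.gene_id, gene_ids):
            raise ValueError("samples must share a gene axis")
    labels = [s.sample_label for s in samples]
    if len(samples) > 1 and reference_label not in labels:
        raise ValueError(f"reference sample {reference_label!r} missing")

    exprs = [normalize_log(s) for s in samples]
    pooled = np.concatenate(exprs, axis=1)
    sample_of_cell = np.concatenate(
        [[s.sample_label] * s.n_cells for s in samples])
    barcodes = [bc for s in samples for bc in s.barcodes]

    n_hvg = min(n_hvg, pooled.shape[0])
    hvg = select_hvg(pooled, list(gene_ids), n_hvg)
    hvg_rows = np.isin(gene_ids, hvg)
    sub = pooled[hvg_rows]
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    k_pcs = min(k_pcs, sub.shape[0], sub.shape[1])
    pcs = run_pca((sub - mu) / sd, k=k_pcs)

    report: dict[str, dict] = {}
    corrected = pcs.copy()
    if len(samples) > 1:
        ref_mask = sample_of_cell == reference_label
        ref_pcs = pcs[ref_mask]
        for lab in dict.fromkeys(labels):
            if lab == reference_label:
                continue
            q_mask = sample_of_cell == lab
            q_pcs = pcs[q_mask]
            pairs = _mnn_pairs(ref_pcs, q_pcs, k_anchor)
            if not pairs:
                warnings.warn(
                    f"sample {lab} shares no anchors with {reference_label}; "
                    "passed through uncorrected")
                report[lab] = {"n_anchors": 0, "corrected": False}
                continue
            ridx = np.array([p[0] for p in pairs])
            qidx = np.array([p[1] for p in pairs])
            disp = ref_pcs[ridx] - q_pcs[qidx]
            anchor_pos = q_pcs[qidx]
            # Gaussian distance weighting of anchor displacements
            d2 = ((q_pcs[:, None, :] - anchor_pos[None, :, :]) ** 2).sum(axis=2)
            sigma2 = np.median(d2) + 1e-12
            w = np.exp(-d2 / (2 * sigma2))
            w /= w.sum(axis=1, keepdims=True)
            corrected[q_mask] = q_pcs + w @ disp
            report[lab] = {"n_anchors": len(pairs), "corrected": True}

    coords = embed_2d(corrected, seed=seed) if compute_umap else None
    knn_idx, knn_dist = build_knn(corrected, n_neighbors=15)
    emb = EmbeddingResult(hvg_ids=hvg, pcs=corrected, coords_2d=coords,
                          knn_indices=knn_idx, knn_distances=knn_dist)
    return {"embedding": emb, "barcodes": barcodes,
            "sample_of_cell": sample_of_cell, "report": report,
            "pcs_uncorrected": pcs}


def classify_by_embedding(
    coords: np.ndarray,
    is_reference: np.ndarray,
    reference_types: np.ndarray,
    k: int = 15,
) -> np.ndarray:
    """Approach 1: majority vote of the k nearest reference cells.

    ``coords`` covers pooled cells; ``reference_types`` gives the cultured
    type ("cancer"/"psc") for reference cells.  Ties -> "unassigned".
    Returns a label per non-reference cell, aligned with their order in
    ``coords``.
    """
    from sklearn.neighbors import NearestNeighbors

    ref_coords = coords[is_reference]
    if k > ref_coords.shape[0]:
        raise ValueError(f"k={k} exceeds reference size {ref_coords.shape[0]}")
    query = coords[~is_reference]
    nn = NearestNeighbors(n_neighbors=k).fit(ref_coords)
    _, idx = nn.kneighbors(query)
    ref_types = np.asarray(reference_types)
    out = np.empty(query.shape[0], dtype=object)
    for i, row in enumerate(idx):
        votes = ref_types[row]
        n_cancer = int((votes == "cancer").sum())
        n_psc = int((votes == "psc").sum())
        if n_cancer > n_psc:
            out[i] = "cancer"
        elif n_psc > n_cancer:
            out[i] = "psc"
        else:
            out[i] = "unassigned"
    return out


def classify_by_clustering(
    knn_indices: np.ndarray,
    is_reference: np.ndarray,
    reference_types: np.ndarray,
    resolution: float = 0.8,
    seed: int = 0,
) -> np.ndarray:
    """Approach 2: cluster the pooled graph, label clusters by Cult majority.

    Clusters with no reference members yield "unassigned" for their cells.
    Returns a label per non-reference cell.
    """
    clusters = cluster_graph(knn_indices, resolution=resolution, seed=seed)
    ref_types = np.asarray(reference_types)
    cluster_label: dict[int, str] = {}
    for c in np.unique(clusters):
        members = clusters == c
        ref_members = members & is_reference
        if not ref_members.any():
            cluster_label[c] = "unassigned"
            continue
        votes = ref_types[ref_members[is_reference]]
        n_cancer = int((votes == "cancer").sum())
        n_psc = int((votes == "psc").sum())
        if n_cancer == n_psc:
            cluster_label[c] = "unassigned"
        else:
            cluster_label[c] = "cancer" if n_cancer > n_psc else "psc"
    return np.array([cluster_label[c] for c in clusters[~is_reference]],
                    dtype=object)


# ---------------------------------------------------------------------------
# Approach 3: reference signature


def build_reference_signature(
    cult: CountMatrix,
    cult_types: np.ndarray,
    n_top: int = DEFAULT_N_TOP,
    alpha: float = 0.05,
) -> ReferenceSignature:
    """Top-N discriminative genes per cultured type from a rank-sum screen.

    Genes are ranked per direction by p-value, ties broken by absolute
    log-fold-change then lexicographic gene id; only genes with rank-sum
    p < ``alpha`` are eligible.  If fewer than ``n_top`` eligible genes
    exist in a direction, all of them are taken with a warning.
    """
    cult_types = np.asarray(cult_types)
    if not {"cancer", "psc"} <= set(cult_types):
        raise ValueError("both cultured types must be present")
    expr = normalize_log(cult)
    a = expr[:, cult_types == "cancer"]
    b = expr[:, cult_types == "psc"]
    z, p = _rank_sum(a, b)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    df = pd.DataFrame({
        "gene_id": cult.genes.gene_id, "z": z, "p": p, "lfc": lfc,
        "direction": np.where(z > 0, "cancer", np.where(z < 0, "psc", "none")),
    })

    def top(direction: str) -> list[str]:
        cand = df[(df["direction"] == direction) & (df["p"] < alpha)].copy()
        cand["abs_lfc"] = cand["lfc"].abs()
        cand = cand.sort_values(["p", "abs_lfc", "gene_id"],
                                ascending=[True, False, True])
        if len(cand) < n_top:
            warnings.warn(
                f"only {len(cand)} significant genes for {direction} "
                f"(requested {n_top}); taking all")
        return cand["gene_id"].head(n_top).tolist()

    return ReferenceSignature(cancer_genes=top("cancer"), psc_genes=top("psc"),
                              scores=df)


def classify_by_signature(
    blood: CountMatrix,
    signature: ReferenceSignature,
    seed: int = 0,
) -> pd.DataFrame:
    """Approach 3: 2-group clustering of blood cells on signature genes only.

    Blood human cells are restricted to the signature genes, log-normalised
    and split by seeded 2-means; each group is labelled by whichever
    signature's mean score dominates among its members.  Per-cell scores are
    the mean normalised expression over each gene list.  A group whose mean
    score margin is exactly zero is "unassigned".

    Returns per-cell rows: ``barcode, score_cancer, score_psc, label``.
    """
    if blood.n_cells < 2:
        raise ValueError("need at least 2 blood human cells")
    sig_genes = list(signature.cancer_genes) + list(signature.psc_genes)
    rows = np.isin(blood.genes.gene_id, sig_genes)
    if not rows.any():
        raise ValueError("no signature genes present in the blood matrix")
    sub = blood.subset_genes(rows)
    # guard: restriction can zero out some cells' counts entirely
    depth = np.asarray(sub.counts.sum(axis=0)).ravel()
    expr = np.zeros((sub.n_genes, sub.n_cells))
    nz = depth > 0
    if nz.any():
        expr[:, nz] = normalize_log(sub.subset_cells(nz))

    in_cancer = np.isin(sub.genes.gene_id, signature.cancer_genes)
    in_psc = np.isin(sub.genes.gene_id, signature.psc_genes)
    score_cancer = expr[in_cancer].mean(axis=0) if in_cancer.any() else np.zeros(sub.n_cells)
    score_psc = expr[in_psc].mean(axis=0) if in_psc.any() else np.zeros(sub.n_cells)

    km = KMeans(n_clusters=2, random_state=seed, n_init=10)
    groups = km.fit_predict(expr.T)
    margin = score_cancer - score_psc
    labels = np.empty(sub.n_cells, dtype=object)
    for g in (0, 1):
        members = groups == g
        m = margin[members].mean()
        if m > 0:
            labels[members] = "cancer"
        elif m < 0:
            labels[members] = "psc"
        else:
            labels[members] = "unassigned"
    return pd.DataFrame({
        "barcode": blood.barcodes,
        "score_cancer": score_cancer,
        "score_psc": score_psc,
        "label": labels,
    })


# ---------------------------------------------------------------------------
# Consensus, transgene test, marker ranking


def consensus_labels(
    a1: pd.Series, a2: pd.Series, a3: pd.Series,
) -> tuple[pd.DataFrame, dict]:
    """Combine the three approach labels into a consensus call per barcode.

    Inputs are barcode-indexed Series with values in
    {"cancer", "psc", "unassigned"} (a barcode absent from an approach, e.g.
    Approach 3 covering blood only, counts as unassigned there).  The
    consensus is a type iff every available (non-unassigned) label agrees
    and at least two approaches reported; otherwise "discordant".

    Returns the per-barcode label frame plus Venn region counts of the
    three approaches' psc sets.
    """
    barcodes = sorted(set(a1.index) | set(a2.index) | set(a3.index))
    frame = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    for name, s in (("label_a1", a1), ("label_a2", a2), ("label_a3", a3)):
        frame[name] = s.reindex(barcodes).fillna("unassigned")

    def consensus(row) -> str:
        avail = [v for v in row if v != "unassigned"]
        if len(avail) >= 2 and len(set(avail)) == 1:
            return avail[0]
        return "discordant"

    frame["consensus"] = frame[["label_a1", "label_a2", "label_a3"]].apply(
        consensus, axis=1)

    sets = {name: set(frame.index[frame[name] == "psc"])
            for name in ("label_a1", "label_a2", "label_a3")}
    s1, s2, s3 = sets["label_a1"], sets["label_a2"], sets["label_a3"]
    venn = {
        "a1_only": len(s1 - s2 - s3),
        "a2_only": len(s2 - s1 - s3),
        "a3_only": len(s3 - s1 - s2),
        "a1_a2": len((s1 & s2) - s3),
        "a1_a3": len((s1 & s3) - s2),
        "a2_a3": len((s2 & s3) - s1),
        "a1_a2_a3": len(s1 & s2 & s3),
    }
    return frame, venn


def transgene_detection_test(
    cpsc_transgene_counts: np.ndarray,
    cancer_transgene_counts: np.ndarray,
) -> dict:
    """Fisher exact test of transgene detection: putative cPSCs vs cancer cells.

    Detection is >= 1 transgene UMI.  Returns the 2x2 table
    ``[[cpsc_detected, cpsc_not], [cancer_detected, cancer_not]]`` and the
    two-sided exact p-value.
    """
    cpsc = np.asarray(cpsc_transgene_counts)
    cancer = np.asarray(cancer_transgene_counts)
    if cpsc.size == 0 or cancer.size == 0:
        raise ValueError("both groups must be non-empty")
    table = np.array([
        [int((cpsc >= 1).sum()), int((cpsc == 0).sum())],
        [int((cancer >= 1).sum()), int((cancer == 0).sum())],
    ])
    _, p = scipy.stats.fisher_exact(table, alternative="two-sided")
    return {"table": table, "p_value": float(p)}


def run_rarecell_pipeline(
    samples: dict[str, CountMatrix],
    reference_types: pd.Series,
    seed: int = 0,
    t_high: float = 0.9,
    t_low: float = 0.1,
    n_top: int = DEFAULT_N_TOP,
    k_vote: int = 15,
    resolution: float = 0.8,
    marker_fdr: float = 0.10,
    compute_umap: bool = True,
) -> dict:
    """End-to-end CTC/cPSC identification on the four compartment samples.

    Demultiplexes species per sample, restricts to human singletons, runs
    the three classification approaches, forms the consensus over blood
    cells, tests transgene non-detection in consensus cPSCs against the
    cancer cells of the mouse-model samples, and ranks CTC-vs-cPSC marker
    genes among Approach-1-labelled blood cells.

    ``reference_types`` maps Cult barcodes to their cultured type
    ("cancer" = AsPC-1, "psc" = cultured PSC).  Returns a dict with the
    species calls, per-approach and consensus labels, Venn counts,
    transgene test and marker table.
    """
    from .demux import assign_species

    required = {"Cult", "MsPrim", "MsSec", "MsBlood"}
    if set(samples) != required:
        raise ValueError(f"samples must cover exactly {sorted(required)}")

    species_calls = {}
    human = {}
    for name, m in samples.items():
        calls = assign_species(m, t_high=t_high, t_low=t_low)
        species_calls[name] = calls
        human[name] = m.subset_cells((calls["call"] == "human").to_numpy())

    order = ["Cult", "MsPrim", "MsSec", "MsBlood"]
    integ = integrate_and_embed([human[s] for s in order], seed=seed,
                                compute_umap=compute_umap)
    emb = integ["embedding"]
    barcodes = np.asarray(integ["barcodes"])
    soc = integ["sample_of_cell"]
    is_ref = soc == "Cult"
    ref_types = reference_types.reindex(barcodes[is_ref]).to_numpy()
    if pd.isna(ref_types).any():
        raise ValueError("reference_types must cover every human Cult barcode")

    space = emb.coords_2d if compute_umap else emb.pcs
    a1 = pd.Series(classify_by_embedding(space, is_ref, ref_types, k=k_vote),
                   index=barcodes[~is_ref])
    a2 = pd.Series(classify_by_clustering(emb.knn_indices, is_ref, ref_types,
                                          resolution=resolution, seed=seed),
                   index=barcodes[~is_ref])

    signature = build_reference_signature(human["Cult"], ref_types, n_top=n_top)
    a3_frame = classify_by_signature(human["MsBlood"], signature, seed=seed)
    a3 = a3_frame.set_index("barcode")["label"]

    labels, venn = consensus_labels(a1, a2, a3)
    bc_sample = dict(zip(barcodes[~is_ref], soc[~is_ref]))
    labels["sample_label"] = [bc_sample.get(bc, "MsBlood") for bc in labels.index]
    labels["circulating"] = labels["sample_label"] == "MsBlood"

    blood = labels[labels["sample_label"] == "MsBlood"]
    cpsc_barcodes = blood.index[blood["consensus"] == "psc"].tolist()
    cancer_barcodes = labels.index[labels["consensus"] == "cancer"].tolist()

    tg = {bc: None for bc in labels.index}
    for name in ("MsPrim", "MsSec", "MsBlood"):
        m = human[name]
        tg_idx = m.genes.transgene_index
        if tg_idx is None:
            continue
        vals = np.asarray(m.counts[tg_idx].todense()).ravel()
        for bc, v in zip(m.barcodes, vals):
            tg[bc] = int(v)
    transgene = None
    if cpsc_barcodes and cancer_barcodes:
        transgene = transgene_detection_test(
            np.array([tg[bc] for bc in cpsc_barcodes]),
            np.array([tg[bc] for bc in cancer_barcodes]))

    markers = None
    ctc_a1 = [bc for bc in blood.index if blood.loc[bc, "label_a1"] == "cancer"]
    cpsc_a1 = [bc for bc in blood.index if blood.loc[bc, "label_a1"] == "psc"]
    if ctc_a1 and cpsc_a1:
        mb = human["MsBlood"]
        expr = normalize_log(mb)
        idx = {bc: i for i, bc in enumerate(mb.barcodes)}
        markers = rank_marker_genes(
            expr[:, [idx[bc] for bc in ctc_a1]],
            expr[:, [idx[bc] for bc in cpsc_a1]],
            list(mb.genes.gene_id), fdr=marker_fdr)

    return {
        "species_calls": species_calls,
        "human": human,
        "integration": integ,
        "signature": signature,
        "labels": labels,
        "venn": venn,
        "cpsc_barcodes": cpsc_barcodes,
        "cancer_barcodes": cancer_barcodes,
        "transgene_test": transgene,
        "markers": markers,
    }


def rank_marker_genes(
    ctc_expr: np.ndarray,
    cpsc_expr: np.ndarray,
    gene_ids: list[str],
    fdr: float = 0.10,
) -> pd.DataFrame:
    """Rank CTC-vs-cPSC marker genes by rank-sum test with BH adjustment.

    ``ctc_expr``/``cpsc_expr`` are genes x cells normalised expression with
    a shared gene axis.  Returns a frame ordered by adjusted p with columns
    ``gene_id, z, p, q, direction, significant`` (``significant`` at the
    requested false-discovery rate).
    """
    if ctc_expr.shape[0] != cpsc_expr.shape[0]:
        raise ValueError("expression tables must share the gene axis")
    z, p = _rank_sum(ctc_expr, cpsc_expr)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    out = pd.DataFrame({
        "gene_id": gene_ids, "z": z, "p": p, "q": q,
        "direction": np.where(z > 0, "ctc", np.where(z < 0, "cpsc", "none")),
        "significant": q < fdr,
    })
    return out.sort_values(["q", "p", "gene_id"]).reset_index(drop=True)
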