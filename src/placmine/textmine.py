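"""Literature mining of gene annotation corpora.

Each gene's abstracts are concatenated into one "gene summary" document.
Summaries are preprocessed (lowercasing, punctuation stripping, removal of
words of three characters or fewer and of stop words, Porter stemming),
expanded into unigram/bigram/trigram terms, and weighted as

    M[i, j] = tf_i * idf_i,     idf_i = log2(|D| / |{d : t_i in d}|),

where tf_i is the count of term i in gene j's summary divided by the total
number of terms in that summary and |D| the number of gene documents.
Gene columns are then length-normalized, embedded with a truncated SVD
(latent semantic analysis), clustered with k-means, and each cluster is
summarized by the terms closest to its center (back-projected through the
SVD loadings) for word-cloud rendering.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import svds
from sklearn.cluster import KMeans
from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

from ._porter import porter_stem

__all__ = [
    "preprocess_text",
    "gene_summaries",
    "build_term_matrix",
    "TermMatrix",
    "fit_lsa",
    "LsaModel",
    "cluster_genes",
    "summarize_clusters",
    "ClusterReport",
]

log = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"[^a-z0-9]+")


def preprocess_text(
    raw: str,
    stopwords=None,
    min_keep_length: int = 4,
    stem: bool = True,
) -> list[str]:
    """Lowercase, strip punctuation, drop short words (< ``min_keep_length``
    characters) and stop words, then Porter-stem each surviving token."""
    if stopwords is None:
        stopwords = ENGLISH_STOP_WORDS
    tokens = [t for t in _TOKEN_RE.split(raw.lower()) if t]
    out = []
    for t in tokens:
        if len(t) < min_keep_length or t in stopwords:
            continue
        out.append(porter_stem(t) if stem else t)
    return out


def gene_summaries(
    docs: dict[str, list[str]],
    stopwords=None,
    min_keep_length: int = 4,
) -> dict[str, list[str]]:
    """Concatenate and preprocess each gene's abstracts into one token
    stream; genes with no abstracts, or whose summaries come out empty,
    are discarded (annotation-free) with a log message."""
    summaries: dict[str, list[str]] = {}
    for gene, abstracts in docs.items():
        tokens: list[str] = []
        for a in abstracts:
            tokens.extend(preprocess_text(a, stopwords=stopwords,
                                          min_keep_length=min_keep_length))
        if tokens:
            summaries[gene] = tokens
        else:
            log.warning("gene %s has no usable annotation; discarded", gene)
    return summaries


@dataclass
class TermMatrix:
    """terms x genes tf-idf matrix with its vocabulary bookkeeping."""

    matrix: sp.csr_matrix
    vocabulary: list[str]
    genes: list[str]
    doc_freq: np.ndarray
    n_docs: int
    raw: sp.csr_matrix | None = field(default=None, repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


def _ngrams(tokens: list[str], orders) -> list[str]:
    grams: list[str] = []
    for k in orders:
        if k == 1:
            grams.extend(tokens)
        else:
            grams.extend(
                " ".join(tokens[i : i + k]) for i in range(len(tokens) - k + 1)
            )
    return grams


def build_term_matrix(
    docs: dict[str, list[str]] | dict[str, list],
    ngram_orders=(1, 2, 3),
    min_df: int = 2,
    norm: str | None = "l2",
    preprocessed: bool = False,
    stopwords=None,
) -> TermMatrix:
    """Build the terms x genes tf-idf matrix.

    ``docs`` maps gene -> list of abstract strings (or, with
    ``preprocessed=True``, gene -> token list).  tf uses one shared
    denominator per gene: the total number of terms of all n-gram orders
    in the summary.  Terms occurring in fewer than ``min_df`` gene
    documents are pruned before weighting.  ``norm`` length-normalizes
    each gene column (``"l1"``, ``"l2"`` or None).
    """
    if preprocessed:
        summaries = {g: list(t) for g, t in docs.items() if t}
    else:
        summaries = gene_summaries(docs, stopwords=stopwords)
    if len(summaries) < 2:
        raise ValueError("need at least 2 non-empty gene documents")
    genes = list(summaries)
    vocab_index: dict[str, int] = {}
    rows, cols, vals = [], [], []
    totals = np.zeros(len(genes))
    for j, g in enumerate(genes):
        grams = _ngrams(summaries[g], ngram_orders)
        totals[j] = len(grams)
        counts: dict[int, int] = {}
        for term in grams:
            i = vocab_index.setdefault(term, len(vocab_index))
            counts[i] = counts.get(i, 0) + 1
        rows.extend(counts.keys())
        cols.extend([j] * len(counts))
        vals.extend(counts.values())
    counts_mat = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(vocab_index), len(genes)), dtype=float
    )
    df = np.asarray((counts_mat > 0).sum(axis=1)).ravel()
    keep = df >= min_df
    vocab = np.array(list(vocab_index))[keep].tolist()
    counts_mat = counts_mat[keep]
    df = df[keep]

    n_docs = len(genes)
    tf = counts_mat.multiply(1.0 / totals[None, :]).tocsr()
    idf = np.log2(n_docs / df)
    raw = sp.csr_matrix(tf.multiply(idf[:, None]))
    M = raw.copy()
    if norm is not None:
        if norm == "l2":
            scale = np.sqrt(np.asarray(M.multiply(M).sum(axis=0)).ravel())
        elif norm == "l1":
            scale = np.asarray(np.abs(M).sum(axis=0)).ravel()
        else:
            raise ValueError("norm must be 'l1', 'l2' or None")
        scale[scale == 0] = 1.0
        M = sp.csr_matrix(M.multiply(1.0 / scale[None, :]))
    return TermMatrix(matrix=M, vocabulary=vocab, genes=genes,
                      doc_freq=df, n_docs=n_docs, raw=raw)


@dataclass
class LsaModel:
    """Truncated-SVD embedding of the term matrix."""

    k: int
    loadings: np.ndarray          # terms x k
    coords: np.ndarray            # genes x k (rows = gene embeddings)
    singular_values: np.ndarray
    retained_variance: float
    vocabulary: list[str]
    genes: list[str]


def fit_lsa(tm: TermMatrix, k: int) -> LsaModel:
    """Latent semantic analysis: rank-``k`` truncated SVD of M.

    Retained variance is the ratio of the sum of squared retained singular
    values to the squared Frobenius norm of M.  ``k`` is capped at the
    effective rank (with a warning), in which case the ratio is ~1.
    """
    M = tm.matrix
    n_terms, n_docs = M.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    requested = k
    k = min(k, n_terms, n_docs)
    fro2 = float(M.multiply(M).sum())
    if fro2 == 0:
        raise ValueError("term matrix is all zeros")
    if k < min(n_terms, n_docs):
        # deterministic start vector for reproducible ARPACK iterations
        v0 = np.full(min(M.shape), 1.0 / np.sqrt(min(M.shape)))
        u, s, vt = svds(M, k=k, v0=v0)
        order = np.argsort(s)[::-1]
        u, s, vt = u[:, order], s[order], vt[order]
    else:
        u_full, s_full, vt_full = np.linalg.svd(M.toarray(), full_matrices=False)
        u, s, vt = u_full[:, :k], s_full[:k], vt_full[:k]
    if requested > min(n_terms, n_docs):
        log.warning("k=%d exceeds matrix rank bound %d; truncated", requested, k)
    retained = float((s**2).sum() / fro2)
    coords = vt.T * s[None, :]
    return LsaModel(
        k=k,
        loadings=u,
        coords=coords,
        singular_values=s,
        retained_variance=min(retained, 1.0),
        vocabulary=tm.vocabulary,
        genes=tm.genes,
    )


def cluster_genes(model: LsaModel, k_clusters: int, seed: int = 0,
                  n_init: int = 10) -> tuple[pd.Series, float]:
    """Lloyd k-means (k-means++ init, ``n_init`` restarts) on the LSA
    coordinates; returns gene -> cluster labels and the within-cluster
    sum of squares."""
    if k_clusters > len(model.genes):
        raise ValueError("k_clusters exceeds the number of genes")
    km = KMeans(n_clusters=k_clusters, n_init=n_init, random_state=seed)
    labels = km.fit_predict(model.coords)
    return pd.Series(labels, index=model.genes, name="cluster"), float(km.inertia_)


@dataclass
class ClusterReport:
    labels: pd.Series
    sizes: pd.Series
    fractions: pd.Series
    top_terms: dict[int, list[tuple[str, float]]]


def summarize_clusters(model: LsaModel, labels: pd.Series, top_m: int = 10) -> ClusterReport:
    """Rank, per cluster, the terms closest to the cluster center.

    The center (mean latent coordinate) is mapped back to term space
    through the SVD loadings; negative back-projected weights are floored
    at zero, and the ``top_m`` highest-weight terms form the word-cloud
    list."""
    labels = labels.loc[model.genes]
    sizes = labels.value_counts().sort_index()
    fractions = sizes / sizes.sum()
    top_m = min(top_m, len(model.vocabulary))
    top: dict[int, list[tuple[str, float]]] = {}
    vocab = np.asarray(model.vocabulary)
    for c in sizes.index:
        center = model.coords[(labels == c).to_numpy()].mean(axis=0)
        weights = model.loadings @ center
        weights = np.maximum(weights, 0.0)
        order = np.argsort(weights)[::-1][:top_m]
        top[int(c)] = [(str(vocab[i]), float(weights[i])) for i in order if weights[i] > 0]
    return ClusterReport(labels=labels, sizes=sizes, fractions=fractions, top_terms=top)
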