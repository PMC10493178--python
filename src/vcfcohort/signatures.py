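"""SBS96 mutational-signature analysis.

A mutational process leaves a characteristic footprint over the 96
single-base-substitution channels: 6 pyrimidine-reference changes
(C>A, C>G, C>T, T>A, T>C, T>G) crossed with the 16 flanking-base contexts,
written ``X[R>A]Y``. Purine-reference SNVs are reverse-complemented so the
reported reference base is always C or T. This module builds the per-sample
channel count matrix from variants + an indexed FASTA, extracts de-novo
signatures by non-negative matrix factorization under the generalized
Kullback-Leibler objective (multiplicative updates, multi-restart), refits
exposures against a fixed signature set by non-negative least squares, and
matches signatures to a reference catalog by cosine similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta
from scipy.optimize import nnls

from .errors import ConfigError, DegenerateInputError, FormatError
from .records import VariantClass, VariantRecord
from .vcf_io import Cohort

#: The 6 strand-collapsed substitution types, in canonical order.
SBS_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: The 96 channel labels, substitution-major then context-lexicographic:
#: A[C>A]A, A[C>A]C, ..., T[T>G]T.
CHANNELS = tuple(
    f"{five}[{sub}]{three}"
    for sub in SBS_TYPES
    for five in "ACGT"
    for three in "ACGT"
)
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def context_channel(trinuc: str, ref: str, alt: str) -> str | None:
    """Channel label from a trinucleotide context and an SNV allele pair.

    ``trinuc`` is the reference trinucleotide centred on the variant.
    Returns None when the context is ambiguous (contains N).
    """
    trinuc = trinuc.upper()
    if len(trinuc) != 3 or any(b not in "ACGT" for b in trinuc):
        return None
    if trinuc[1] != ref:
        raise FormatError(
            f"context {trinuc} center does not match ref allele {ref}"
        )
    if ref in "AG":  # purine reference: reverse-complement the strand
        trinuc = _revcomp(trinuc)
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    return f"{trinuc[0]}[{ref}>{alt}]{trinuc[2]}"


def trinucleotide_context(v: VariantRecord, genome: Fasta) -> str | None:
    """SBS96 channel of an SNV given an indexed FASTA; None if dropped.

    Drops (returns None) SNVs at a chromosome end or whose flanks contain N.
    """
    if v.vclass is not VariantClass.SNV:
        raise ConfigError("trinucleotide context is defined for SNVs only")
    if v.chrom not in genome:
        raise FormatError(f"chromosome {v.chrom!r} missing from reference FASTA")
    chrom_len = len(genome[v.chrom])
    if v.pos < 2 or v.pos > chrom_len - 1:
        return None
    trinuc = str(genome[v.chrom][v.pos - 2 : v.pos + 1]).upper()
    if trinuc[1] != v.ref:
        raise FormatError(
            f"reference mismatch at {v.chrom}:{v.pos}: FASTA {trinuc[1]} vs REF {v.ref}"
        )
    return context_channel(trinuc, v.ref, v.alt)


@dataclass
class SBS96Matrix:
    """96 x n_samples channel count matrix with per-sample drop counts."""

    counts: pd.DataFrame  # index = CHANNELS, columns = samples
    dropped: pd.Series  # per-sample dropped SNVs (ambiguous context/boundary)

    def __post_init__(self) -> None:
        if tuple(self.counts.index) != CHANNELS:
            raise FormatError("SBS96 matrix rows must be the 96 channels in order")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def values(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=float)


def build_sbs96(cohort: Cohort, genome: str | Path | Fasta) -> SBS96Matrix:
    """Channel counts per sample over a cohort's SNVs."""
    fa = genome if isinstance(genome, Fasta) else Fasta(str(genome))
    samples = cohort.samples
    mat = pd.DataFrame(0, index=list(CHANNELS), columns=samples, dtype=int)
    dropped = pd.Series(0, index=samples, dtype=int)
    for sample in samples:
        for r in cohort.variants[sample]:
            if r.vclass is not VariantClass.SNV:
                continue
            channel = trinucleotide_context(r, fa)
            if channel is None:
                dropped[sample] += 1
            else:
                mat.loc[channel, sample] += 1
    return SBS96Matrix(mat, dropped)


# --- de-novo extraction (KL-NMF, multiplicative updates) -------------------

_EPS = 1e-12


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    """Generalized KL divergence D(V || WH) = sum V log(V/WH) - V + WH."""
    mask = V > 0
    div = np.sum(WH) - np.sum(V)
    div += np.sum(V[mask] * np.log(V[mask] / np.maximum(WH[mask], _EPS)))
    return float(div)


def _nmf_kl(
    V: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    n_chan, n_samp = V.shape
    scale = np.sqrt(V.mean() / k)
    W = rng.uniform(_EPS, 1.0, size=(n_chan, k)) * scale
    H = rng.uniform(_EPS, 1.0, size=(k, n_samp)) * scale
    prev = np.inf
    for it in range(max_iter):
        WH = np.maximum(W @ H, _EPS)
        H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        WH = np.maximum(W @ H, _EPS)
        W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        if it % 10 == 9 or it == max_iter - 1:
            obj = _kl_divergence(V, np.maximum(W @ H, _EPS))
            if np.isfinite(prev) and prev - obj <= tol * max(abs(obj), 1.0):
                prev = obj
                break
            prev = obj
    obj = _kl_divergence(V, np.maximum(W @ H, _EPS))
    return W, H, obj


def extract_signatures(
    m: SBS96Matrix,
    k: int,
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-8,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """De-novo NMF signature extraction.

    Factorizes the 96 x n count matrix as W (signatures) x H (exposures)
    minimizing generalized KL divergence, keeping the best of ``n_restarts``
    random initializations; deterministic for a given (seed, n_restarts).
    Signature columns are rescaled to sum to 1, with the scale absorbed
    into exposures, so exposures are attributed mutation counts.

    Returns (signatures 96 x k, exposures k x samples, reconstruction error).
    """
    V = m.values()
    n_samples = V.shape[1]
    if k < 1 or k > min(96, n_samples):
        raise ConfigError(f"k={k} outside [1, min(96, n_samples={n_samples})]")
    if n_restarts < 1:
        raise ConfigError("n_restarts must be >= 1")
    if not V.any():
        raise DegenerateInputError("all-zero SBS96 matrix")
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(n_restarts):
        W, H, obj = _nmf_kl(V, k, rng, max_iter, tol)
        if best is None or obj < best[2]:
            best = (W, H, obj)
    W, H, obj = best
    col = np.maximum(W.sum(axis=0), _EPS)
    W = W / col
    H = H * col[:, None]
    names = [f"Sig{i + 1}" for i in range(k)]
    sigs = pd.DataFrame(W, index=list(CHANNELS), columns=names)
    expo = pd.DataFrame(H, index=names, columns=m.samples)
    return sigs, expo, obj


def fit_exposures(m: SBS96Matrix, refs: pd.DataFrame) -> pd.DataFrame:
    """Refit per-sample exposures onto fixed reference signatures (NNLS).

    ``refs`` is a 96 x k column-stochastic frame indexed by channel label in
    canonical order. Returns a k x n_samples exposure frame in mutation
    counts.
    """
    if tuple(refs.index) != CHANNELS:
        raise FormatError("reference signatures must use the canonical channel order")
    R = refs.to_numpy(dtype=float)
    if (R < -1e-12).any():
        raise FormatError("reference signatures must be non-negative")
    V = m.values()
    out = np.zeros((R.shape[1], V.shape[1]))
    for j in range(V.shape[1]):
        out[:, j], _ = nnls(R, V[:, j])
    return pd.DataFrame(out, index=list(refs.columns), columns=m.samples)


def cosine_similarity_matrix(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Pairwise cosine similarities between signature columns of a and b."""
    if tuple(a.index) != tuple(b.index):
        raise FormatError("signature frames must share channel order")
    A = a.to_numpy(dtype=float)
    B = b.to_numpy(dtype=float)
    na = np.maximum(np.linalg.norm(A, axis=0), _EPS)
    nb = np.maximum(np.linalg.norm(B, axis=0), _EPS)
    sim = (A / na).T @ (B / nb)
    return pd.DataFrame(sim, index=list(a.columns), columns=list(b.columns))


def match_to_catalog(
    sigs: pd.DataFrame, catalog: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Best catalog match per signature.

    Returns (match table with columns signature/best_match/cosine,
    full similarity matrix).
    """
    sim = cosine_similarity_matrix(sigs, catalog)
    best = sim.idxmax(axis=1)
    rows = [
        {"signature": s, "best_match": best[s], "cosine": float(sim.loc[s, best[s]])}
        for s in sim.index
    ]
    return pd.DataFrame(rows, columns=["signature", "best_match", "cosine"]), sim


def rank_scan(
    m: SBS96Matrix,
    k_values: list[int],
    n_restarts: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Reconstruction error and restart stability per candidate rank.

    Stability is the mean cosine of greedily matched signature pairs across
    all restart pairs; no rank is auto-selected.
    """
    rows = []
    V = m.values()
    rng = np.random.default_rng(seed)
    for k in k_values:
        sets = []
        errors = []
        for _ in range(n_restarts):
            W, H, obj = _nmf_kl(V, k, rng, max_iter=2000, tol=1e-8)
            W = W / np.maximum(W.sum(axis=0), _EPS)
            sets.append(pd.DataFrame(W, index=list(CHANNELS)))
            errors.append(obj)
        cosines = []
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                sim = cosine_similarity_matrix(sets[i], sets[j]).to_numpy()
                cosines.append(_greedy_match_mean(sim))
        rows.append(
            {
                "k": k,
                "reconstruction_error": float(min(errors)),
                "stability": float(np.mean(cosines)) if cosines else 1.0,
            }
        )
    return pd.DataFrame(rows, columns=["k", "reconstruction_error", "stability"])


def _greedy_match_mean(sim: np.ndarray) -> float:
    sim = sim.copy()
    k = sim.shape[0]
    vals = []
    for _ in range(k):
        i, j = np.unravel_index(np.argmax(sim), sim.shape)
        vals.append(sim[i, j])
        sim[i, :] = -np.inf
        sim[:, j] = -np.inf
    return float(np.mean(vals))


# --- catalog / matrix I/O ---------------------------------------------------


def write_sbs96(m: SBS96Matrix, path: str | Path) -> None:
    df = m.counts.copy()
    df.insert(0, "Type", df.index)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_signature_tsv(path: str | Path) -> pd.DataFrame:
    """Read a COSMIC-style signature/catalog TSV (Type column + signatures).

    Rows are reordered into the canonical channel order; a missing or
    incomplete channel set is a format error.
    """
    df = pd.read_csv(path, sep="\t")
    type_col = df.columns[0]
    df = df.set_index(type_col)
    missing = set(CHANNELS) - set(df.index)
    if missing:
        raise FormatError(
            f"{path}: catalog missing {len(missing)} channels (e.g. {sorted(missing)[:3]})"
        )
    return df.loc[list(CHANNELS)]


def read_sbs96(path: str | Path) -> SBS96Matrix:
    df = read_signature_tsv(path).astype(int)
    return SBS96Matrix(df, pd.Series(0, index=df.columns, dtype=int))


def write_signatures(sigs: pd.DataFrame, path: str | Path) -> None:
    out = sigs.copy()
    out.insert(0, "Type", out.index)
    out.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.10g")
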