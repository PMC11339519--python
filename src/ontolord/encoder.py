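"""The text-encoder contract shared by all training phases.

Every phase (contrastive, self-distillation, weight averaging, cross-lingual
distillation) and every evaluation sees an encoder only through this surface:
``encode`` maps a list of texts to a matrix of unit-norm embeddings, and
``parameters`` exposes a flat, stably-ordered collection of named arrays.
Similarity is cosine on the normalized vectors throughout, so it reduces to a
dot product.

The trainable reference implementation, :class:`HashingNgramEncoder`, hashes
character n-grams into a fixed number of buckets (the hashing trick, murmur3)
and applies a trainable linear map followed by L2 normalization.  It is small
enough to train on one CPU in seconds, which makes the whole pipeline
exercisable without pretrained weights; heavyweight pretrained sentence
encoders can be plugged in behind the same contract via
:class:`FunctionEncoder`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Callable, Protocol, runtime_checkable

import numpy as np
import scipy.sparse as sp
from sklearn.utils.murmurhash import murmurhash3_32

from .exceptions import ConfigurationError, InputError

_NORM_FLOOR = 1e-12


@runtime_checkable
class Encoder(Protocol):
    """Structural contract: anything with these members can drive the pipeline."""

    dimension: int
    architecture_tag: str

    def encode(self, texts: list[str], normalize: bool = True) -> np.ndarray: ...

    def parameters(self) -> dict[str, np.ndarray]: ...


def _check_texts(texts: list[str]) -> None:
    for i, t in enumerate(texts):
        if not isinstance(t, str) or t == "":
            raise InputError(f"text at index {i} is empty or not a string")


def encode_texts(enc: Encoder, texts: list[str], normalize: bool = True) -> np.ndarray:
    """Order-preserving batch encoding; one row per input text."""
    _check_texts(texts)
    return enc.encode(texts, normalize=normalize)


def char_ngrams(text: str, ngram_range: tuple[int, int]) -> list[str]:
    """All character n-grams of ``text`` for n in the inclusive range.

    A text shorter than the smallest n contributes itself as a single feature
    so that no input ever has an empty feature set.
    """
    lo, hi = ngram_range
    grams = [text[i : i + n] for n in range(lo, hi + 1) for i in range(len(text) - n + 1)]
    return grams or [text]


class HashingNgramEncoder:
    """Character-n-gram hashing encoder with a trainable linear projection.

    Pipeline: text -> n-gram counts hashed into ``hash_buckets`` (L2-normalized
    counts) -> linear map ``W`` (dimension x hash_buckets) -> L2 normalization.
    Deterministic in inference; initialization reproducible from ``seed``.
    """

    def __init__(
        self,
        dimension: int = 64,
        hash_buckets: int = 16384,
        ngram_range: tuple[int, int] = (2, 3),
        seed: int = 0,
        init_scale: float = 0.05,
    ):
        if dimension < 2:
            raise ConfigurationError("dimension must be >= 2")
        if hash_buckets < dimension:
            raise ConfigurationError("hash_buckets must be >= dimension")
        if ngram_range[0] > ngram_range[1] or ngram_range[0] < 1:
            raise ConfigurationError(f"invalid ngram_range {ngram_range!r}")
        self.dimension = int(dimension)
        self.hash_buckets = int(hash_buckets)
        self.ngram_range = (int(ngram_range[0]), int(ngram_range[1]))
        self.seed = int(seed)
        self.init_scale = float(init_scale)
        rng = np.random.default_rng(seed)
        self.W = rng.normal(0.0, init_scale, size=(self.dimension, self.hash_buckets))
        self._feature_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    @property
    def architecture_tag(self) -> str:
        lo, hi = self.ngram_range
        return f"hashing-ngram/D{self.dimension}/H{self.hash_buckets}/n{lo}-{hi}"

    # ---- featurization -------------------------------------------------

    def _features(self, text: str) -> tuple[np.ndarray, np.ndarray]:
        cached = self._feature_cache.get(text)
        if cached is not None:
            return cached
        buckets: dict[int, float] = {}
        for gram in char_ngrams(text, self.ngram_range):
            b = murmurhash3_32(gram, seed=0, positive=True) % self.hash_buckets
            buckets[b] = buckets.get(b, 0.0) + 1.0
        idx = np.fromiter(buckets.keys(), dtype=np.int64, count=len(buckets))
        val = np.fromiter(buckets.values(), dtype=np.float64, count=len(buckets))
        val /= np.linalg.norm(val)
        order = np.argsort(idx)
        out = (idx[order], val[order])
        self._feature_cache[text] = out
        return out

    def features_matrix(self, texts: list[str]) -> sp.csr_matrix:
        indptr = [0]
        indices: list[np.ndarray] = []
        data: list[np.ndarray] = []
        for t in texts:
            idx, val = self._features(t)
            indices.append(idx)
            data.append(val)
            indptr.append(indptr[-1] + len(idx))
        return sp.csr_matrix(
            (np.concatenate(data) if data else np.empty(0),
             np.concatenate(indices) if indices else np.empty(0, dtype=np.int64),
             np.asarray(indptr)),
            shape=(len(texts), self.hash_buckets),
        )

    # ---- inference -----------------------------------------------------

    def encode(self, texts: list[str], normalize: bool = True) -> np.ndarray:
        _check_texts(texts)
        C = self.features_matrix(texts)
        U = np.asarray(C @ self.W.T)
        if not normalize:
            return U
        norms = np.maximum(np.linalg.norm(U, axis=1, keepdims=True), _NORM_FLOOR)
        return U / norms

    # ---- training support ----------------------------------------------

    def forward(self, texts: list[str]) -> tuple[np.ndarray, tuple]:
        """Normalized embeddings plus a cache for :meth:`backward` /
        :meth:`sgd_update`.

        Uses flat (feature index, value, row) arrays rather than a sparse
        matrix: each batch touches only a few hundred of the hash columns, so
        gathers and scatters on those columns beat full sparse-dense products.
        """
        _check_texts(texts)
        feats = [self._features(t) for t in texts]
        counts = np.array([len(i) for i, _ in feats])
        idxs = np.concatenate([i for i, _ in feats])
        data = np.concatenate([v for _, v in feats])
        starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
        rows = np.repeat(np.arange(len(texts)), counts)
        contrib = self.W[:, idxs].T * data[:, None]  # (nnz, D)
        U = np.add.reduceat(contrib, starts, axis=0)
        norms = np.maximum(np.linalg.norm(U, axis=1, keepdims=True), _NORM_FLOOR)
        E = U / norms
        return E, (idxs, data, rows, E, norms)

    @staticmethod
    def _input_grad(cache: tuple, dE: np.ndarray) -> np.ndarray:
        """Backprop through the normalization: gradient w.r.t. U = W c."""
        _idxs, _data, _rows, E, norms = cache
        return (dE - (dE * E).sum(axis=1, keepdims=True) * E) / norms

    def backward(self, cache: tuple, dE: np.ndarray) -> dict[str, np.ndarray]:
        """Dense gradient of a scalar loss w.r.t. W given its gradient w.r.t.
        the normalized embeddings."""
        idxs, data, rows, _E, _norms = cache
        dU = self._input_grad(cache, dE)
        gW = np.zeros_like(self.W)
        contrib = dU[rows] * data[:, None]  # (nnz, D)
        np.add.at(gW.T, idxs, contrib)
        return {"W": gW}

    def apply_gradients(self, grads: dict[str, np.ndarray], learning_rate: float) -> None:
        self.W -= learning_rate * grads["W"]

    def sgd_update(self, grads: list[tuple[tuple, np.ndarray]], learning_rate: float) -> None:
        """One SGD step from (cache, dE) pairs, touching only active columns."""
        all_idxs, all_contrib = [], []
        for cache, dE in grads:
            idxs, data, rows, _E, _norms = cache
            dU = self._input_grad(cache, dE)
            all_idxs.append(idxs)
            all_contrib.append(dU[rows] * data[:, None])
        idxs = np.concatenate(all_idxs)
        contrib = np.concatenate(all_contrib)
        cols, pos = np.unique(idxs, return_inverse=True)
        G = np.zeros((len(cols), self.dimension))
        np.add.at(G, pos, contrib)
        self.W[:, cols] -= learning_rate * G.T

    # ---- parameter plumbing ---------------------------------------------

    def parameters(self) -> dict[str, np.ndarray]:
        return {"W": self.W}

    def set_parameters(self, params: dict[str, np.ndarray]) -> None:
        if set(params) != {"W"} or params["W"].shape != self.W.shape:
            raise ConfigurationError("parameter collection incompatible with this encoder")
        self.W = np.array(params["W"], dtype=np.float64, copy=True)

    def copy(self) -> "HashingNgramEncoder":
        clone = HashingNgramEncoder(self.dimension, self.hash_buckets, self.ngram_range, self.seed, self.init_scale)
        clone.W = self.W.copy()
        clone._feature_cache = self._feature_cache  # read-only shared cache
        return clone


class FunctionEncoder:
    """Adapter exposing any ``texts -> (n, D) array`` callable as an Encoder.

    Intended for plugging pretrained sentence encoders (inference only; it has
    no trainable parameters as far as the pipeline is concerned).
    """

    def __init__(self, fn: Callable[[list[str]], np.ndarray], dimension: int, tag: str = "external"):
        self._fn = fn
        self.dimension = dimension
        self.architecture_tag = tag

    def encode(self, texts: list[str], normalize: bool = True) -> np.ndarray:
        _check_texts(texts)
        E = np.asarray(self._fn(texts), dtype=np.float64)
        if E.shape != (len(texts), self.dimension):
            raise InputError(f"external encoder returned shape {E.shape}")
        if normalize:
            norms = np.maximum(np.linalg.norm(E, axis=1, keepdims=True), _NORM_FLOOR)
            E = E / norms
        return E

    def parameters(self) -> dict[str, np.ndarray]:
        return {}


def make_reference_encoder(
    dimension: int = 64,
    hash_buckets: int = 16384,
    ngram_range: tuple[int, int] = (2, 3),
    seed: int = 0,
    init_scale: float = 0.05,
) -> HashingNgramEncoder:
    """Factory for the trainable desk-scale reference encoder."""
    return HashingNgramEncoder(dimension, hash_buckets, ngram_range, seed, init_scale)


# ---- checkpoints ---------------------------------------------------------


def save_encoder(enc: HashingNgramEncoder, directory: str | Path) -> Path:
    """Checkpoint = manifest.json + weights.npz under one directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "type": "hashing_ngram",
        "dimension": enc.dimension,
        "hash_buckets": enc.hash_buckets,
        "ngram_range": list(enc.ngram_range),
        "seed": enc.seed,
        "init_scale": enc.init_scale,
        "architecture_tag": enc.architecture_tag,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    np.savez(directory / "weights.npz", **enc.parameters())
    return directory


def load_encoder(directory: str | Path) -> HashingNgramEncoder:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    if manifest["type"] != "hashing_ngram":
        raise ConfigurationError(f"unknown encoder type {manifest['type']!r}")
    enc = HashingNgramEncoder(
        manifest["dimension"],
        manifest["hash_buckets"],
        tuple(manifest["ngram_range"]),
        manifest["seed"],
        manifest.get("init_scale", 0.05),
    )
    with np.load(directory / "weights.npz") as arrays:
        enc.set_parameters({k: arrays[k] for k in arrays.files})
    return enc
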