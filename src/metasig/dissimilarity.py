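"""The eight k-tuple dissimilarity measures and pairwise matrices.

Cosine-type measures are reported as (1 - cos)/2 so that identical
signatures score 0:

* ``d2``      -- uncentered cosine on raw count vectors; range [0, 0.5]
  because raw counts are nonnegative.
* ``d2s``     -- self-standardised centered statistic: with centered counts
  Xt_w = X_w - n_X p^X_w, D = sum Xt Yt / sqrt(Xt^2 + Yt^2) and analogous
  norms A, B; value (1 - D/sqrt(AB))/2 in [0, 1].
* ``d2star``  -- expectation-standardised: D* = sum Xt Yt / sqrt(E_X E_Y)
  with E = n p_w; value (1 - D*/sqrt(A* B*))/2 in [0, 1] by Cauchy-Schwarz.
* ``hao``     -- CVTree composition vectors a_w = (f - f0)/f0 with f0 the
  (k-2)-order Markov expectation; (1 - cos)/2 in [0, 1].

Plus the relative-entropy measure ``s2`` and the Manhattan / Euclidean /
Chebyshev distances on relative frequency vectors (``ma``, ``eu``, ``ch``).

Validity: an order-r centered measure is defined only for k >= r+1; hao only
for k >= 3. Invalid combinations yield an NA-flagged matrix, never silent
zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DegenerateSampleError,
    FormatError,
    LabelError,
    NotApplicableError,
    ParameterError,
)
from .kmer_signature import KTupleSignature, count_ktuples
from .markov_background import (
    MarkovModel,
    cvtree_expected_frequencies,
    fit_markov,
    floored_probabilities,
    word_probabilities,
)
from .sequence_io import ReadSet

#: measure name -> needs a Markov order
MEASURES: dict[str, bool] = {
    "d2": False,
    "d2s": True,
    "d2star": True,
    "s2": True,
    "hao": False,  # order is implicitly k-2
    "ma": False,
    "eu": False,
    "ch": False,
}

_LP_VARIANTS = {"manhattan": "ma", "euclidean": "eu", "chebyshev": "ch"}


def is_valid_combination(measure: str, k: int, order: int | None) -> bool:
    """NA-validity rule: order-r centerings need k >= r+1; hao needs k >= 3."""
    if measure not in MEASURES:
        raise ParameterError(f"unknown measure {measure!r}")
    if k < 1:
        return False
    if measure == "hao":
        return k >= 3
    if MEASURES[measure]:
        if order is None:
            raise ParameterError(f"measure {measure!r} requires a Markov order")
        return k >= order + 1
    return True


@dataclass
class CenteredSignature:
    """Centered count vector Xt_w = X_w - n p_w of one sample."""

    sample_id: str
    k: int
    order: int
    centered: np.ndarray
    expectations: np.ndarray  # n * p_w, floored where an observed word had p=0
    n: int


def center_signature(sig: KTupleSignature, model: MarkovModel) -> CenteredSignature:
    """Center a signature under its sample's background model."""
    p = word_probabilities(model, sig.k)  # raises NotApplicableError if k < r+1
    p = floored_probabilities(p, sig.counts, model)
    expect = sig.n * p
    return CenteredSignature(
        sample_id=sig.sample_id,
        k=sig.k,
        order=model.order,
        centered=sig.counts - expect,
        expectations=expect,
        n=sig.n,
    )


def d2(sigX: KTupleSignature, sigY: KTupleSignature) -> float:
    """Uncentered (1 - cosine)/2 on raw count vectors; in [0, 0.5]."""
    if sigX.k != sigY.k:
        raise ParameterError(f"tuple sizes differ: {sigX.k} vs {sigY.k}")
    x = sigX.counts.astype(float)
    y = sigY.counts.astype(float)
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise DegenerateSampleError("zero-norm count vector")
    cos = float(x @ y) / (nx * ny)
    return float(np.clip((1.0 - cos) / 2.0, 0.0, 1.0))


def d2s(csX: CenteredSignature, csY: CenteredSignature) -> float:
    """Self-standardised centered dissimilarity; in [0, 1].

    Words with Xt_w = Yt_w = 0 are skipped (their term is 0/0 and
    contributes nothing to D, A or B).
    """
    _check_centered_pair(csX, csY)
    xt, yt = csX.centered, csY.centered
    denom = np.sqrt(xt**2 + yt**2)
    mask = denom > 0
    d = float(np.sum(xt[mask] * yt[mask] / denom[mask]))
    a = float(np.sum(xt[mask] ** 2 / denom[mask]))
    b = float(np.sum(yt[mask] ** 2 / denom[mask]))
    if a == 0 or b == 0:
        raise DegenerateSampleError("all-zero centered vector in d2s")
    return float(np.clip((1.0 - d / np.sqrt(a * b)) / 2.0, 0.0, 1.0))


def d2star(csX: CenteredSignature, csY: CenteredSignature) -> float:
    """Expectation-standardised centered dissimilarity; in [0, 1]."""
    _check_centered_pair(csX, csY)
    xt, yt = csX.centered, csY.centered
    ex, ey = csX.expectations, csY.expectations
    # E = 0 implies count = 0 (flooring) hence Xt = 0: the term is 0, skip it.
    mask = (ex > 0) & (ey > 0)
    d = float(np.sum(xt[mask] * yt[mask] / np.sqrt(ex[mask] * ey[mask])))
    a = float(np.sum(np.where(ex > 0, xt**2 / np.where(ex > 0, ex, 1.0), 0.0)))
    b = float(np.sum(np.where(ey > 0, yt**2 / np.where(ey > 0, ey, 1.0), 0.0)))
    if a == 0 or b == 0:
        raise DegenerateSampleError("all-zero centered vector in d2star")
    return float(np.clip((1.0 - d / np.sqrt(a * b)) / 2.0, 0.0, 1.0))


def _check_centered_pair(csX: CenteredSignature, csY: CenteredSignature) -> None:
    if csX.k != csY.k:
        raise ParameterError(f"tuple sizes differ: {csX.k} vs {csY.k}")
    if csX.order != csY.order:
        raise ParameterError(f"Markov orders differ: {csX.order} vs {csY.order}")


def lp_distance(freqX: np.ndarray, freqY: np.ndarray, variant: str) -> float:
    """Manhattan / Euclidean / Chebyshev distance on frequency vectors."""
    freqX = np.asarray(freqX, dtype=float)
    freqY = np.asarray(freqY, dtype=float)
    if freqX.shape != freqY.shape:
        raise ParameterError(f"shape mismatch: {freqX.shape} vs {freqY.shape}")
    diff = freqX - freqY
    if variant in ("manhattan", "ma"):
        return float(np.abs(diff).sum())
    if variant in ("euclidean", "eu"):
        return float(np.sqrt((diff**2).sum()))
    if variant in ("chebyshev", "ch"):
        return float(np.abs(diff).max())
    raise ParameterError(f"unknown Lp variant {variant!r}")


def composition_vector(
    sig_k: KTupleSignature, sig_km1: KTupleSignature, sig_km2: KTupleSignature
) -> np.ndarray:
    """CVTree composition vector a_w = (f(w) - f0(w)) / f0(w), 0 where f0=0."""
    f0 = cvtree_expected_frequencies(sig_k, sig_km1, sig_km2)
    f = sig_k.frequencies()
    return np.divide(f - f0, f0, out=np.zeros_like(f), where=f0 > 0)


def hao(
    sigsX: tuple[KTupleSignature, KTupleSignature, KTupleSignature],
    sigsY: tuple[KTupleSignature, KTupleSignature, KTupleSignature],
) -> float:
    """CVTree dissimilarity (1 - cos)/2 on composition vectors; in [0, 1].

    Each argument is the sample's signature triple at (k, k-1, k-2).
    """
    aX = composition_vector(*sigsX)
    aY = composition_vector(*sigsY)
    nx, ny = np.linalg.norm(aX), np.linalg.norm(aY)
    if nx == 0 or ny == 0:
        raise DegenerateSampleError("zero-norm composition vector in hao")
    cos = float(aX @ aY) / (nx * ny)
    return float(np.clip((1.0 - cos) / 2.0, 0.0, 1.0))


def s2(
    sigX: KTupleSignature,
    sigY: KTupleSignature,
    mX: MarkovModel,
    mY: MarkovModel,
    form: str = "cross",
) -> float:
    """Relative-entropy dissimilarity (natural log); nonnegative.

    S2 = sum_i F_X(i) ln(F_X(i)/P_i) + sum_i F_Y(i) ln(F_Y(i)/Q_i), where F
    are observed k-tuple frequencies and P, Q are order-r Markov word
    probabilities. ``form="cross"`` (default) takes P from sample Y's model
    and Q from sample X's; ``form="self"`` pairs each sample with its own
    model. Terms with F = 0 contribute 0; zero probabilities facing a
    positive frequency are floored at 1/(10*n).
    """
    if sigX.k != sigY.k:
        raise ParameterError(f"tuple sizes differ: {sigX.k} vs {sigY.k}")
    if form not in ("cross", "self"):
        raise ParameterError(f"unknown S2 form {form!r}")
    k = sigX.k
    pX = word_probabilities(mX, k)
    pY = word_probabilities(mY, k)
    if form == "cross":
        p_for_X, model_for_X = pY, mY
        p_for_Y, model_for_Y = pX, mX
    else:
        p_for_X, model_for_X = pX, mX
        p_for_Y, model_for_Y = pY, mY

    def one_side(sig: KTupleSignature, p: np.ndarray, m: MarkovModel) -> float:
        f = sig.frequencies()
        p = floored_probabilities(p, sig.counts, m)
        mask = f > 0
        return float(np.sum(f[mask] * np.log(f[mask] / p[mask])))

    return one_side(sigX, p_for_X, model_for_X) + one_side(sigY, p_for_Y, model_for_Y)


@dataclass
class DissimilarityMatrix:
    """Labelled symmetric dissimilarity matrix for one (measure, k, order)."""

    labels: list[str]
    values: np.ndarray
    measure: str
    k: int
    order: int | None = None
    valid: bool = True
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise FormatError(
                f"matrix shape {self.values.shape} inconsistent with {n} labels"
            )
        if len(set(self.labels)) != n:
            raise LabelError("duplicate sample ids in matrix labels")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"#measure={self.measure}\n")
            fh.write(f"#k={self.k}\n")
            fh.write(f"#order={'NA' if self.order is None else self.order}\n")
            fh.write(f"#valid={'yes' if self.valid else 'NA'}\n")
            self.to_dataframe().to_csv(fh, sep="\t", index_label="sample")
        return path

    @classmethod
    def read(cls, path: str | Path) -> "DissimilarityMatrix":
        path = Path(path)
        header: dict[str, str] = {}
        body: list[str] = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    key, _, value = line[1:].rstrip("\n").partition("=")
                    header[key] = value
                else:
                    body.append(line)
        from io import StringIO

        df = pd.read_csv(StringIO("".join(body)), sep="\t", index_col=0)
        order = None if header.get("order", "NA") == "NA" else int(header["order"])
        return cls(
            labels=list(df.index),
            values=df.to_numpy(),
            measure=header.get("measure", "unknown"),
            k=int(header.get("k", 0)),
            order=order,
            valid=header.get("valid", "yes") == "yes",
        )


def pairwise_matrix(
    samples: list[ReadSet],
    measure: str,
    k: int,
    order: int | None = None,
    s2_form: str = "cross",
) -> DissimilarityMatrix:
    """Dissimilarity matrix over a sample panel for one (measure, k, order).

    Per-sample artifacts (signatures, background models, centered vectors)
    are computed once and reused across all pairs. An invalid combination
    returns an all-NA matrix flagged ``valid=False``.
    """
    labels = [rs.sample_id for rs in samples]
    if len(labels) < 2:
        raise ParameterError("need at least 2 samples")
    if len(set(labels)) != len(labels):
        raise LabelError(f"duplicate sample ids: {labels}")
    n = len(samples)
    if not is_valid_combination(measure, k, order):
        return DissimilarityMatrix(
            labels=labels,
            values=np.full((n, n), np.nan),
            measure=measure,
            k=k,
            order=order,
            valid=False,
        )

    sigs = [count_ktuples(rs, k) for rs in samples]
    values = np.zeros((n, n))

    if measure == "d2":
        pair = lambda i, j: d2(sigs[i], sigs[j])
    elif measure in ("ma", "eu", "ch"):
        freqs = [s.frequencies() for s in sigs]
        pair = lambda i, j: lp_distance(freqs[i], freqs[j], measure)
    elif measure in ("d2s", "d2star"):
        models = [fit_markov(rs, order) for rs in samples]
        centered = [center_signature(s, m) for s, m in zip(sigs, models)]
        fn = d2s if measure == "d2s" else d2star
        pair = lambda i, j: fn(centered[i], centered[j])
    elif measure == "s2":
        models = [fit_markov(rs, order) for rs in samples]
        pair = lambda i, j: s2(sigs[i], sigs[j], models[i], models[j], form=s2_form)
    elif measure == "hao":
        sigs_km1 = [count_ktuples(rs, k - 1) for rs in samples]
        sigs_km2 = [count_ktuples(rs, k - 2) for rs in samples]
        comp = [
            composition_vector(sk, s1, s2_)
            for sk, s1, s2_ in zip(sigs, sigs_km1, sigs_km2)
        ]
        norms = np.array([np.linalg.norm(a) for a in comp])
        if (norms == 0).any():
            raise DegenerateSampleError("zero-norm composition vector in hao")

        def pair(i: int, j: int) -> float:
            cos = float(comp[i] @ comp[j]) / (norms[i] * norms[j])
            return float(np.clip((1.0 - cos) / 2.0, 0.0, 1.0))

    else:  # pragma: no cover - guarded by is_valid_combination
        raise ParameterError(f"unknown measure {measure!r}")

    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = pair(i, j)
    return DissimilarityMatrix(
        labels=labels, values=values, measure=measure, k=k, order=order, valid=True
    )
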