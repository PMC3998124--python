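"""Individual-information (Ri) scoring models for fixed-width DNA motifs.

A model is built from an aligned collection of experimentally validated
binding sites.  Each position contributes a weight of ``2 + log2 f(b, l)``
bits for base *b* at position *l*, where ``f`` is the per-position relative
base frequency (uniform genomic background assumed).  The score of a
sequence is the sum of its per-position weights; sites resembling the
collection score near the motif's information content, unrelated sequence
scores near zero or below.

The collection also fixes the operating threshold used downstream: sites
scoring more than 1.5 standard deviations below the collection mean are
discarded.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Score reported for a sequence that uses a base never observed at a
#: position (frequency 0 under pseudocount 0).  Kept as IEEE -inf so that
#: any threshold comparison rejects it.
NEG_INF = float("-inf")


class MotifError(ValueError):
    """Raised for malformed site collections or sequences."""


@dataclass(frozen=True)
class SiteCollection:
    """An aligned collection of equal-length binding sites (ACGT only)."""

    sites: tuple[str, ...]
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.sites:
            raise MotifError("site collection is empty")
        width = len(self.sites[0])
        if width < 4:
            raise MotifError(f"site width {width} < 4")
        for i, s in enumerate(self.sites):
            if len(s) != width:
                raise MotifError(
                    f"site {i} has length {len(s)}, expected {width}"
                )
            if any(c not in _BASE_INDEX for c in s):
                raise MotifError(f"site {i} contains non-ACGT characters: {s}")
        if self.labels is not None and len(self.labels) != len(self.sites):
            raise MotifError("labels and sites differ in length")

    @property
    def width(self) -> int:
        return len(self.sites[0])

    def __len__(self) -> int:
        return len(self.sites)

    @classmethod
    def from_sequences(
        cls, sites: Iterable[str], labels: Iterable[str] | None = None
    ) -> "SiteCollection":
        return cls(
            tuple(s.upper() for s in sites),
            tuple(labels) if labels is not None else None,
        )

    @classmethod
    def from_fasta(cls, path: str | Path) -> "SiteCollection":
        from Bio import SeqIO

        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise MotifError(f"no sequences in {path}")
        return cls.from_sequences(
            (str(r.seq) for r in records), (r.id for r in records)
        )

    @classmethod
    def from_text(cls, path: str | Path) -> "SiteCollection":
        """One site per line; blank lines and ``#`` comments ignored."""
        lines = [
            ln.strip()
            for ln in Path(path).read_text().splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
        return cls.from_sequences(lines)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, s in enumerate(self.sites):
                label = self.labels[i] if self.labels else f"site_{i + 1}"
                fh.write(f">{label}\n{s}\n")


@dataclass(frozen=True)
class ScoringModel:
    """Per-position frequencies and Ri weights for a fixed-width motif.

    Attributes
    ----------
    freq
        ``(L, 4)`` relative base frequencies, columns ordered A, C, G, T.
        Each row sums to 1.
    riw
        ``(L, 4)`` Ri weights in bits, ``2 + log2 freq`` (minus the
        small-sample correction when enabled).  ``-inf`` marks bases never
        observed under pseudocount 0.
    pseudocount
        Pseudocount (in count units) added to every cell before
        normalising.
    mean, sd
        Mean and standard deviation (bits) of the scores of the collection
        the model was built from.  For a model constructed directly from a
        frequency matrix these are the analytic mean and SD of sites drawn
        from the matrix itself.
    """

    freq: np.ndarray
    riw: np.ndarray
    pseudocount: float
    mean: float
    sd: float
    small_sample_correction: bool = False
    sd_mode: str = "population"

    @property
    def width(self) -> int:
        return self.freq.shape[0]

    @property
    def threshold(self) -> float:
        """Collection-derived operating threshold: mean − 1.5·SD (bits)."""
        return self.mean - 1.5 * self.sd

    def score(self, seq: str) -> float:
        return score_sequence(self, seq)

    @property
    def max_score(self) -> float:
        """Best achievable score: sum of per-position maximum weights."""
        return float(self.riw.max(axis=1).sum())

    @classmethod
    def from_frequencies(
        cls, freq: np.ndarray, small_sample_correction: bool = False, n_sites: int = 0
    ) -> "ScoringModel":
        """Build a model directly from an ``(L, 4)`` frequency matrix.

        ``mean`` and ``sd`` are the analytic moments of the score of a site
        sampled position-wise from ``freq``; ``mean`` therefore equals the
        matrix's information content (Rsequence).
        """
        freq = np.asarray(freq, dtype=float)
        if freq.ndim != 2 or freq.shape[1] != 4:
            raise MotifError("frequency matrix must have shape (L, 4)")
        if not np.allclose(freq.sum(axis=1), 1.0, atol=1e-9):
            raise MotifError("frequency matrix rows must sum to 1")
        riw = _weights_from_freq(freq)
        if small_sample_correction:
            if n_sites <= 0:
                raise MotifError("small-sample correction requires n_sites > 0")
            riw = riw - _small_sample_error(n_sites)
        mean, sd = _analytic_score_moments(freq, riw)
        return cls(
            freq=freq,
            riw=riw,
            pseudocount=math.nan,
            mean=mean,
            sd=sd,
            small_sample_correction=small_sample_correction,
        )

    # -- serialization --------------------------------------------------

    def write(self, matrix_path: str | Path, meta_path: str | Path) -> None:
        """Write the frequency/weight matrix (TSV) and a JSON sidecar."""
        with open(matrix_path, "w") as fh:
            header = (
                ["position"]
                + [f"f_{b}" for b in BASES]
                + [f"riw_{b}" for b in BASES]
            )
            fh.write("\t".join(header) + "\n")
            for l in range(self.width):
                row = (
                    [str(l + 1)]
                    + [f"{self.freq[l, i]:.10g}" for i in range(4)]
                    + [f"{self.riw[l, i]:.10g}" for i in range(4)]
                )
                fh.write("\t".join(row) + "\n")
        meta = {
            "width": self.width,
            "pseudocount": self.pseudocount,
            "mean": self.mean,
            "sd": self.sd,
            "threshold": self.threshold,
            "small_sample_correction": self.small_sample_correction,
            "sd_mode": self.sd_mode,
        }
        Path(meta_path).write_text(json.dumps(meta, indent=2) + "\n")

    @classmethod
    def read(cls, matrix_path: str | Path, meta_path: str | Path) -> "ScoringModel":
        meta = json.loads(Path(meta_path).read_text())
        rows = Path(matrix_path).read_text().splitlines()
        freq, riw = [], []
        for ln in rows[1:]:
            parts = ln.split("\t")
            freq.append([float(x) for x in parts[1:5]])
            riw.append([float(x) for x in parts[5:9]])
        return cls(
            freq=np.array(freq),
            riw=np.array(riw),
            pseudocount=meta["pseudocount"],
            mean=meta["mean"],
            sd=meta["sd"],
            small_sample_correction=meta.get("small_sample_correction", False),
            sd_mode=meta.get("sd_mode", "population"),
        )


def _weights_from_freq(freq: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return 2.0 + np.log2(freq)


def _small_sample_error(n: int) -> float:
    """Approximate per-position sampling bias e(n) in bits for 4 letters.

    First-order approximation (4 − 1) / (2·ln 2·n) to the expected
    overestimate of information content from n sampled sites; subtracting
    it from every weight applies the correction uniformly across positions.
    """
    return 3.0 / (2.0 * math.log(2.0) * n)


def _analytic_score_moments(freq: np.ndarray, riw: np.ndarray) -> tuple[float, float]:
    w = np.where(freq > 0, riw, 0.0)  # zero-frequency bases never drawn
    contrib = freq * w
    mean = float(contrib.sum())
    var = float(((freq * w**2).sum(axis=1) - contrib.sum(axis=1) ** 2).sum())
    return mean, math.sqrt(max(var, 0.0))


def build_scoring_model(
    collection: SiteCollection,
    pseudocount: float = 0.0,
    small_sample_correction: bool = False,
    sd_mode: str = "population",
) -> ScoringModel:
    """Build an Ri scoring model from an aligned site collection.

    Parameters
    ----------
    collection
        Aligned, equal-length ACGT sites.
    pseudocount
        Added to every base count before normalising:
        ``f(b,l) = (n(b,l) + a) / (N + 4a)``.  The default 0 reproduces the
        literal frequency matrix of the collection; bases never observed
        then carry a ``-inf`` weight.
    small_sample_correction
        Subtract the per-position sampling-bias term e(N) from every
        weight (off by default).
    sd_mode
        ``"population"`` (divide by N; default — the collection is treated
        as the full reference set) or ``"sample"`` (divide by N − 1).

    Returns
    -------
    ScoringModel
        With ``mean``/``sd`` computed by scoring every collection member,
        hence ``threshold = mean − 1.5·sd``.
    """
    if pseudocount < 0:
        raise MotifError("pseudocount must be >= 0")
    if sd_mode not in ("population", "sample"):
        raise MotifError(f"unknown sd_mode {sd_mode!r}")
    L = collection.width
    counts = np.zeros((L, 4), dtype=float)
    for s in collection.sites:
        for l, c in enumerate(s):
            counts[l, _BASE_INDEX[c]] += 1.0
    n = len(collection)
    freq = (counts + pseudocount) / (n + 4.0 * pseudocount)
    riw = _weights_from_freq(freq)
    if small_sample_correction:
        riw = riw - _small_sample_error(n)
    scores = np.array(
        [_score_indices(riw, _encode(s)) for s in collection.sites]
    )
    mean = float(scores.mean())
    ddof = 0 if sd_mode == "population" else 1
    sd = float(scores.std(ddof=ddof)) if n > ddof else 0.0
    return ScoringModel(
        freq=freq,
        riw=riw,
        pseudocount=pseudocount,
        mean=mean,
        sd=sd,
        small_sample_correction=small_sample_correction,
        sd_mode=sd_mode,
    )


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise MotifError(f"ambiguous or invalid base {exc.args[0]!r} in {seq!r}")


def _score_indices(riw: np.ndarray, idx: np.ndarray) -> float:
    return float(riw[np.arange(len(idx)), idx].sum())


def score_sequence(model: ScoringModel, seq: str) -> float:
    """Ri score (bits) of a single sequence of the model's width.

    A position whose base was never observed in the collection (frequency 0
    under pseudocount 0) makes the score ``-inf``.
    """
    seq = seq.upper()
    if len(seq) != model.width:
        raise MotifError(
            f"sequence length {len(seq)} != model width {model.width}"
        )
    return _score_indices(model.riw, _encode(seq))


def rsequence(model: ScoringModel) -> float:
    """Expected information per site (bits): sum of f(b,l)·riw(b,l).

    Entries with zero frequency contribute 0 (their -inf weight is never
    realised when sampling from the model).  Equals the expected Ri score
    of a site sampled position-wise from the model's frequencies.
    """
    w = np.where(model.freq > 0, model.riw, 0.0)
    return float((model.freq * w).sum())


def sample_site(model: ScoringModel, rng: np.random.Generator) -> str:
    """Draw one site, each position sampled independently from f(·, l)."""
    out = []
    for l in range(model.width):
        out.append(BASES[rng.choice(4, p=model.freq[l])])
    return "".join(out)


def sample_sites(
    model: ScoringModel, n: int, rng: np.random.Generator
) -> list[str]:
    """Draw ``n`` sites from the model (vectorised equivalent of
    repeated :func:`sample_site` draws, same per-position distribution)."""
    cols = [
        rng.choice(4, size=n, p=model.freq[l]) for l in range(model.width)
    ]
    mat = np.stack(cols, axis=1)
    return ["".join(BASES[i] for i in row) for row in mat]
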