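"""Adult, auxiliary and group lexicons.

A lexicon is a row-stochastic matrix over referents and words: entry
``(r, w)`` is the probability ``P(w | r)`` that a speaker utters word ``w``
when talking about referent ``r``.  Rows with several non-zero entries
encode within-speaker variance (the same speaker labelling the same
referent in different ways); zero entries are words that speaker never
uses for that referent.

Three roles are played by the same matrix type:

* the *adult* lexicon ``A`` a child learns from,
* the *auxiliary* lexicon ``F`` from which diverse adult idiolects are
  sampled, and
* the *group* lexicon ``G`` (entrywise mean of all adults) against which
  the child's progress is scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

#: Tolerance for the row-stochasticity invariant.
ROW_SUM_TOL = 1e-9

#: Entries below this absolute threshold count as exact zeros.  Shipped
#: lexicons only ever contain simple rationals, so the threshold is never
#: load-bearing; it merely guards against representation noise in files.
ZERO_TOL = 1e-12


@dataclass(frozen=True)
class LexiconMatrix:
    """A row-stochastic referent-by-word probability matrix.

    Parameters
    ----------
    probs : array-like of shape (R, W)
        ``probs[r, w] = P(w | r)``.  Every row must sum to 1 (within
        ``ROW_SUM_TOL``), all entries must be non-negative, and at least
        two referents are required (one interaction shows the child two
        distinct referents).
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.array(self.probs, dtype=float)
        if probs.ndim != 2:
            raise ValueError(f"lexicon must be a 2-D matrix, got ndim={probs.ndim}")
        if probs.shape[0] < 2:
            raise ValueError(
                f"need at least 2 referents (an interaction draws two distinct "
                f"referents), got {probs.shape[0]}"
            )
        if probs.shape[1] < 1:
            raise ValueError("need at least one word")
        if np.any(probs < 0):
            raise ValueError("lexicon entries must be non-negative")
        bad = np.abs(probs.sum(axis=1) - 1.0) > ROW_SUM_TOL
        if np.any(bad):
            rows = np.nonzero(bad)[0]
            raise ValueError(f"lexicon rows {rows.tolist()} do not sum to 1")
        probs.flags.writeable = False
        object.__setattr__(self, "probs", probs)

    @property
    def n_referents(self) -> int:
        return self.probs.shape[0]

    @property
    def n_words(self) -> int:
        return self.probs.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.probs.shape

    def row(self, r: int) -> np.ndarray:
        """The word-use distribution for referent ``r`` (0-based)."""
        return self.probs[r]


@dataclass(frozen=True)
class Population:
    """A community of adult speakers with a common (R, W) vocabulary.

    ``source`` optionally records the auxiliary lexicon the idiolects were
    sampled from, and ``samples_per_referent`` the sample count ``s`` used
    (fewer samples = more between-speaker diversity).
    """

    adults: tuple[LexiconMatrix, ...]
    source: Optional[LexiconMatrix] = None
    samples_per_referent: Optional[int] = None

    def __post_init__(self) -> None:
        adults = tuple(self.adults)
        if len(adults) < 1:
            raise ValueError("population needs at least one adult")
        shape = adults[0].shape
        for k, a in enumerate(adults):
            if a.shape != shape:
                raise ValueError(
                    f"adult {k} has shape {a.shape}, expected {shape}: all adults "
                    "must share the same referent and word inventory"
                )
        object.__setattr__(self, "adults", adults)

    @property
    def n_adults(self) -> int:
        return len(self.adults)

    @property
    def shape(self) -> tuple[int, int]:
        return self.adults[0].shape


def make_tridiagonal(n_words: int) -> LexiconMatrix:
    """The square tri-diagonal lexicon used throughout the simulations.

    Row 1 is (0.75, 0.25, 0, ...), each interior row r puts mass 0.25 on
    word r-1, 0.5 on word r and 0.25 on word r+1, and the last row is
    (..., 0.25, 0.75).  Every column also sums to 1, which makes the
    no-forgetting error plateau exactly 1/(2(R-1)).
    """
    if n_words < 2:
        raise ValueError(f"tridiagonal lexicon needs n_words >= 2, got {n_words}")
    n = n_words
    probs = np.zeros((n, n))
    idx = np.arange(n)
    probs[idx, idx] = 0.5
    probs[idx[:-1], idx[:-1] + 1] = 0.25
    probs[idx[1:], idx[1:] - 1] = 0.25
    probs[0, 0] = 0.75
    probs[n - 1, n - 1] = 0.75
    return LexiconMatrix(probs)


def sample_adult_lexicon(
    aux: LexiconMatrix, s: int, rng: np.random.Generator
) -> LexiconMatrix:
    """Sample one adult idiolect from the auxiliary lexicon.

    For each referent independently, ``s`` word tokens are drawn from the
    auxiliary distribution and the adult's row is the empirical frequency
    vector of those draws.  Small ``s`` yields coarse, high-variance
    idiolects; as ``s`` grows the idiolect converges to the auxiliary
    lexicon.  The sampled support is always contained in the auxiliary
    support.
    """
    if s < 1:
        raise ValueError(f"samples per referent must be >= 1, got {s}")
    pvals = aux.probs / aux.probs.sum(axis=1, keepdims=True)
    counts = rng.multinomial(s, pvals)
    return LexiconMatrix(counts / s)


def sample_population(
    aux: LexiconMatrix, n_adults: int, s: int, rng: np.random.Generator
) -> Population:
    """Sample ``n_adults`` independent idiolects from ``aux``."""
    adults = tuple(sample_adult_lexicon(aux, s, rng) for _ in range(n_adults))
    return Population(adults, source=aux, samples_per_referent=s)


def group_lexicon(pop: Population) -> LexiconMatrix:
    """Entrywise mean of the adult lexicons — the learning target."""
    stack = np.stack([a.probs for a in pop.adults])
    return LexiconMatrix(stack.mean(axis=0))


def zero_support(lex: LexiconMatrix, r: int) -> np.ndarray:
    """Word indices (0-based) that are never used for referent ``r``.

    These are the cells whose child-lexicon mass counts as an error; the
    returned array's length is W0(r).
    """
    if not 0 <= r < lex.n_referents:
        raise IndexError(f"referent index {r} out of range [0, {lex.n_referents})")
    return np.nonzero(lex.probs[r] <= ZERO_TOL)[0]


# ---------------------------------------------------------------------------
# Plain-text serialization
# ---------------------------------------------------------------------------

def write_lexicon_tsv(lex: LexiconMatrix, path: Union[str, Path]) -> None:
    """Write a lexicon as TSV with 1-based referent labels and w1..wW header."""
    path = Path(path)
    with path.open("w") as fh:
        header = "referent\t" + "\t".join(f"w{j + 1}" for j in range(lex.n_words))
        fh.write(header + "\n")
        for r in range(lex.n_referents):
            cells = "\t".join(repr(float(v)) for v in lex.probs[r])
            fh.write(f"{r + 1}\t{cells}\n")


def read_lexicon_tsv(path: Union[str, Path]) -> LexiconMatrix:
    """Read a lexicon written by :func:`write_lexicon_tsv` (validates rows)."""
    path = Path(path)
    rows: list[list[float]] = []
    with path.open() as fh:
        header = fh.readline().strip().split("\t")
        if not header or header[0] != "referent":
            raise ValueError(f"{path}: first column of the header must be 'referent'")
        n_words = len(header) - 1
        for line_no, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != n_words + 1:
                raise ValueError(f"{path}:{line_no}: expected {n_words + 1} columns")
            rows.append([float(v) for v in cells[1:]])
    return LexiconMatrix(np.array(rows))
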