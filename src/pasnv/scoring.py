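"""Cleavage/polyadenylation scorers and the log-odds-ratio (LOR) statistic.

A *scorer* maps a 205-nt window centred on a cleavage site to an aggregate
cleavage probability in the open interval (0, 1).  The variant-effect
statistic is the difference of logits between the mutant and wild-type
windows::

    LOR = ln(mut / (1 - mut)) - ln(wt / (1 - wt))

Any object with a ``score(sequence) -> float`` method honouring the
open-interval contract can drive the pipeline; a published deep-learning
model can be plugged in through :class:`ExternalCommandScorer` without a
code dependency.  The built-in :class:`SurrogateScorer` is a deterministic
logistic model over polyadenylation-signal hexamer counts, calibrated so
that loss of a proximal AATAAA is the strongest single-nucleotide effect.
"""

from __future__ import annotations

import logging
import math
import re
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

logger = logging.getLogger(__name__)

#: half-width of the scoring window around the cleavage site, in nt
WINDOW_FLANK = 102
#: total window length (cleavage site base plus WINDOW_FLANK on each side)
WINDOW_LENGTH = 2 * WINDOW_FLANK + 1

_VALID_SEQ = re.compile(r"^[ACGT]+$")

# overlapping-match lookaheads; every start position is counted
_RE_AATAAA = re.compile(r"(?=AATAAA)")
_RE_ATTAAA = re.compile(r"(?=ATTAAA)")


class ScorerError(ValueError):
    """Raised for sequences or probabilities violating the scorer contract."""


@runtime_checkable
class Scorer(Protocol):
    """Contract: deterministic aggregate cleavage probability in (0, 1)."""

    def score(self, sequence: str) -> float:  # pragma: no cover - protocol
        ...


def logistic(x: float) -> float:
    """Numerically stable standard logistic function."""
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    z = math.exp(x)
    return z / (1.0 + z)


def logit(p: float) -> float:
    if not 0.0 < p < 1.0:
        raise ScorerError(f"probability must lie strictly in (0, 1); got {p}")
    return math.log(p / (1.0 - p))


@dataclass(frozen=True)
class SurrogateParams:
    """Coefficients of the logistic surrogate scorer.

    The intercept places a signal-free window near zero cleavage
    probability; a single proximal AATAAA lifts it to exactly 0.5 so that
    losing that hexamer yields LOR = -4, well past the |LOR| >= 1
    classification threshold, while the weaker ATTAAA contributes 2.5 and
    distal background AWTAAA occurrences only 0.5 each.
    """

    beta0: float = -4.0
    beta_aataaa: float = 4.0
    beta_attaaa: float = 2.5
    beta_bg: float = 0.5
    #: closed interval of hexamer *start* offsets (relative to the cleavage
    #: site at offset 0) treated as the proximal signal region
    proximal_start: int = -40
    proximal_end: int = -5


def _validate_window(sequence: str, flank: int) -> None:
    expected = 2 * flank + 1
    if len(sequence) != expected:
        raise ScorerError(
            f"window must be {expected} nt for flank {flank}; got {len(sequence)}"
        )
    if not _VALID_SEQ.match(sequence):
        raise ScorerError("window contains characters outside {A,C,G,T}")


def _starts(pattern: re.Pattern, sequence: str) -> list[int]:
    return [m.start() for m in pattern.finditer(sequence)]


class SurrogateScorer:
    """Deterministic hexamer-count logistic scorer.

    score = logistic(beta0 + beta_aataaa * n1 + beta_attaaa * n2 + beta_bg * n3)

    where n1 and n2 count overlapping AATAAA / ATTAAA start positions whose
    offset lies in the proximal region, and n3 counts AWTAAA starts anywhere
    else in the window.
    """

    def __init__(self, params: SurrogateParams | None = None, flank: int = WINDOW_FLANK):
        self.params = params or SurrogateParams()
        self.flank = flank

    def score(self, sequence: str) -> float:
        _validate_window(sequence, self.flank)
        p = self.params
        n1 = n2 = n3 = 0
        for start in _starts(_RE_AATAAA, sequence):
            offset = start - self.flank
            if p.proximal_start <= offset <= p.proximal_end:
                n1 += 1
            else:
                n3 += 1
        for start in _starts(_RE_ATTAAA, sequence):
            offset = start - self.flank
            if p.proximal_start <= offset <= p.proximal_end:
                n2 += 1
            else:
                n3 += 1
        return logistic(p.beta0 + p.beta_aataaa * n1 + p.beta_attaaa * n2 + p.beta_bg * n3)


class ExternalCommandScorer:
    """Adapter invoking an external scoring model as a subprocess.

    The command is run as ``<command> <input.fa> <output.tsv>``; the input
    is a FASTA of windows and the output a two-column (id, probability)
    table.  Probabilities at or beyond the open-interval boundary are
    clamped to [eps, 1-eps] with a logged warning, because the LOR is
    undefined at 0 and 1.
    """

    def __init__(self, command: Sequence[str], flank: int = WINDOW_FLANK, eps: float = 1e-9):
        self.command = list(command)
        self.flank = flank
        self.eps = eps

    def score_batch(self, sequences: Sequence[str]) -> list[float]:
        for seq in sequences:
            _validate_window(seq, self.flank)
        with tempfile.TemporaryDirectory() as tmp:
            fa = Path(tmp) / "windows.fa"
            out = Path(tmp) / "scores.tsv"
            with open(fa, "w") as fh:
                for i, seq in enumerate(sequences):
                    fh.write(f">w{i}\n{seq}\n")
            subprocess.run([*self.command, str(fa), str(out)], check=True)
            scores: dict[str, float] = {}
            with open(out) as fh:
                for line in fh:
                    if not line.strip():
                        continue
                    key, value = line.split()[:2]
                    scores[key] = float(value)
        result = []
        for i in range(len(sequences)):
            p = scores[f"w{i}"]
            clamped = min(max(p, self.eps), 1.0 - self.eps)
            if clamped != p:
                logger.warning("external score %g clamped to %g", p, clamped)
            result.append(clamped)
        return result

    def score(self, sequence: str) -> float:
        return self.score_batch([sequence])[0]


@dataclass(frozen=True)
class LorResult:
    """Wild-type and mutant cleavage probabilities with their LOR."""

    wt: float
    mut: float
    lor: float


def compute_lor(wt: float, mut: float) -> float:
    """Log odds ratio of mutant vs wild-type cleavage probability.

    Antisymmetric in its arguments; raises :class:`ScorerError` if either
    probability sits at 0 or 1, which the scorer contract forbids.
    """
    return logit(mut) - logit(wt)


def score_pair(scorer: Scorer, wt_window: str, mut_window: str) -> LorResult:
    """Score a wild-type/mutant window pair and return the LOR."""
    wt = scorer.score(wt_window)
    mut = scorer.score(mut_window)
    return LorResult(wt=wt, mut=mut, lor=compute_lor(wt, mut))
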