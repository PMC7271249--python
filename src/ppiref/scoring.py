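"""Evidence-based confidence scoring of protein-protein interactions.

Each interaction gets a score ``S = w_s*s_s + w_o*s_o + w_t*s_t`` where the
three sub-scores share the saturating form::

    s_i(n) = 2 / (1 + exp(-alpha_i * n)) - 1        in [0, 1)

(algebraically ``tanh(alpha_i * n / 2)``).  ``n`` is, respectively, the
number of supporting studies, the number of non-mouse species whose homolog
pairs also interact (interologs), and the sum of expert reliability values
(0-10) over the distinct detection techniques used.  Weights default to
0.6/0.1/0.3 and rates to 1/1.5/0.5, so the study sub-score saturates around
three studies, the interolog sub-score around two species, and the technique
sub-score once roughly two mid-reliability techniques have been applied.

Confidence levels are quartiles of the score distribution: the medium
threshold is the median and the high threshold the upper quartile.  The
published reference-network values, 0.53 and 0.6, ship as named presets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigError, ParseError
from .mitab import EvidenceBundle

#: Published preset thresholds of the reference score distribution.
MEDIUM_CONFIDENCE = 0.53
HIGH_CONFIDENCE = 0.6

CONFIDENCE_PRESETS = {"medium": MEDIUM_CONFIDENCE, "high": HIGH_CONFIDENCE}

#: Expert-assigned technique reliabilities (0-10) for the anchor classes:
#: structure/biophysics-grade assays 10, classic binary/complex assays 5,
#: imaging- or perturbation-based approaches 1.
DEFAULT_RELIABILITY: dict[str, tuple[str, float]] = {
    "MI:0077": ("nuclear magnetic resonance", 10.0),
    "MI:0067": ("light scattering", 10.0),
    "MI:0018": ("two hybrid", 5.0),
    "MI:0019": ("coimmunoprecipitation", 5.0),
    "MI:0416": ("fluorescence microscopy", 1.0),
    "MI:0231": ("rnai", 1.0),
}

#: Fallback reliability for detection methods absent from the table
#: (the lowest anchor class).
DEFAULT_UNKNOWN_RELIABILITY = 1.0


@dataclass
class ScoreConfig:
    """Weights, saturation rates and the technique-reliability table.

    Weights must be nonnegative and sum to 1; rates must be positive;
    reliabilities must lie in [0, 10].
    """

    w_s: float = 0.6
    w_o: float = 0.1
    w_t: float = 0.3
    alpha_s: float = 1.0
    alpha_o: float = 1.5
    alpha_t: float = 0.5
    reliability: dict[str, float] = field(
        default_factory=lambda: {mi: rel for mi, (_, rel) in DEFAULT_RELIABILITY.items()}
    )
    unknown_reliability: float = DEFAULT_UNKNOWN_RELIABILITY
    warn_unknown: bool = True

    def validate(self) -> None:
        weights = (self.w_s, self.w_o, self.w_t)
        if any(w < 0 for w in weights):
            raise ConfigError(f"weights must be nonnegative, got {weights}")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ConfigError(f"weights must sum to 1, got {sum(weights)!r}")
        if min(self.alpha_s, self.alpha_o, self.alpha_t) <= 0:
            raise ConfigError("saturation rates must be positive")
        for code, rel in self.reliability.items():
            if not (0.0 <= rel <= 10.0):
                raise ConfigError(
                    f"reliability of {code} is {rel}, outside [0, 10]"
                )
        if not (0.0 <= self.unknown_reliability <= 10.0):
            raise ConfigError("unknown-method reliability outside [0, 10]")


def default_score_config() -> ScoreConfig:
    return ScoreConfig()


@dataclass(frozen=True)
class ScoredInteraction:
    """A protein pair with its confidence score, sub-scores and evidence."""

    pair: tuple[int, int]
    score: float
    s_s: float
    s_o: float
    s_t: float
    evidence: EvidenceBundle


def subscore(n: float, alpha: float) -> float:
    """Saturating sub-score ``2/(1+exp(-alpha*n)) - 1``.

    Strictly increasing in ``n``, zero at ``n = 0`` and bounded below 1.
    """
    if n < 0:
        raise ValueError(f"evidence quantity must be nonnegative, got {n}")
    if alpha <= 0:
        raise ValueError(f"saturation rate must be positive, got {alpha}")
    return 2.0 / (1.0 + math.exp(-alpha * n)) - 1.0


def technique_evidence(techniques: Iterable[str], config: ScoreConfig) -> float:
    """Sum of reliability values over the *distinct* technique codes.

    Reliability counts once per technique no matter how many studies used
    it.  Codes missing from the table contribute
    ``config.unknown_reliability`` (with a warning by default).
    """
    total = 0.0
    for code in set(techniques):
        rel = config.reliability.get(code)
        if rel is None:
            if config.warn_unknown:
                warnings.warn(
                    f"detection method {code} has no reliability entry; "
                    f"using default {config.unknown_reliability}",
                    stacklevel=2,
                )
            rel = config.unknown_reliability
        total += rel
    return total


def confidence_score(
    bundle: EvidenceBundle, config: ScoreConfig | None = None
) -> ScoredInteraction:
    """Score one evidence bundle.

    ``n`` for the study sub-score is the study count, for the interolog
    sub-score the non-mouse species count, and for the technique sub-score
    the summed reliability of the distinct techniques.
    """
    if config is None:
        config = ScoreConfig()
    config.validate()
    s_s = subscore(len(bundle.studies), config.alpha_s)
    s_o = subscore(len(bundle.interolog_species), config.alpha_o)
    s_t = subscore(technique_evidence(bundle.techniques, config), config.alpha_t)
    score = config.w_s * s_s + config.w_o * s_o + config.w_t * s_t
    return ScoredInteraction(bundle.pair, score, s_s, s_o, s_t, bundle)


def rescore(
    bundles: Mapping[tuple[int, int], EvidenceBundle] | Iterable[EvidenceBundle],
    config: ScoreConfig | None = None,
) -> list[ScoredInteraction]:
    """Score every bundle under ``config``; deterministic (sorted by pair).

    This is the entry point for re-scoring the whole reference or a subset
    with user-specified reliabilities, weights or saturation rates.
    """
    if isinstance(bundles, Mapping):
        items: Iterable[EvidenceBundle] = bundles.values()
    else:
        items = bundles
    return [confidence_score(b, config) for b in sorted(items, key=lambda b: b.pair)]


def confidence_levels(scores: Sequence[float]) -> dict[str, float]:
    """Quartile-based confidence thresholds of a score distribution.

    ``medium`` is the median (50th percentile) and ``high`` the upper
    quartile (75th percentile), computed with the linear-interpolation
    quantile.  For the published reference-network constants use
    :data:`CONFIDENCE_PRESETS` instead.
    """
    scores = list(scores)
    if not scores:
        raise ValueError("confidence levels require a nonempty score multiset")
    medium, high = np.percentile(scores, [50, 75])
    return {"medium": float(medium), "high": float(high)}


def load_reliability_table(path: str | Path) -> dict[str, float]:
    """Read a reliability TSV with columns (mi_code, name, reliability)."""
    table: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("mi_code\t"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected 3 columns, got {len(parts)}"
                )
            try:
                table[parts[0]] = float(parts[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-numeric reliability {parts[2]!r}"
                ) from exc
    return table


def reliability_by_name(name: str) -> float:
    """Look up a default-table reliability by method name (case-insensitive)."""
    for code, (method, rel) in DEFAULT_RELIABILITY.items():
        if method.lower() == name.lower():
            return rel
    raise KeyError(name)


def write_scored_tsv(scored: Sequence[ScoredInteraction], path: str | Path) -> None:
    """Write scored interactions (and their evidence) to a TSV."""
    with open(path, "w") as fh:
        fh.write(
            "entrez_a\tentrez_b\tscore\ts_s\ts_o\ts_t\t"
            "studies\ttechniques\tinterolog_species\tinteraction_types\n"
        )
        for si in scored:
            ev = si.evidence
            fh.write(
                "\t".join(
                    [
                        str(si.pair[0]),
                        str(si.pair[1]),
                        repr(si.score),
                        repr(si.s_s),
                        repr(si.s_o),
                        repr(si.s_t),
                        "|".join(sorted(ev.studies)),
                        "|".join(sorted(ev.techniques)),
                        "|".join(sorted(ev.interolog_species)),
                        "|".join(sorted(ev.interaction_types)),
                    ]
                )
                + "\n"
            )


def read_scored_tsv(path: str | Path) -> list[ScoredInteraction]:
    """Inverse of :func:`write_scored_tsv`."""
    out: list[ScoredInteraction] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("entrez_a\t"):
            raise ParseError(f"{path}: line 1: missing scored-TSV header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 10:
                raise ParseError(
                    f"{path}: line {lineno}: expected 10 columns, got {len(parts)}"
                )
            pair = (int(parts[0]), int(parts[1]))
            bundle = EvidenceBundle(
                pair=pair,
                studies={s for s in parts[6].split("|") if s},
                techniques={s for s in parts[7].split("|") if s},
                interolog_species={s for s in parts[8].split("|") if s},
                interaction_types={s for s in parts[9].split("|") if s},
            )
            out.append(
                ScoredInteraction(
                    pair,
                    float(parts[2]),
                    float(parts[3]),
                    float(parts[4]),
                    float(parts[5]),
                    bundle,
                )
            )
    return out
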