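"""Electronic-Northern statistics for a three-tissue EST expression table.

Given per-gene integer TPM values in mammary (ma), skin (s) and muscle (mu)
tissue, this module computes

* **percent mammary transcript abundance** for gene *x*::

      pct(x) = 100 * TPM_ma(x) / sum over ALL genes of TPM_ma

  The denominator runs over every gene in the table, including genes whose
  EST profile is incomplete.

* the **mammary/skin TPM ratio**, ``TPM_ma / TPM_s``, reported only when
  both values are positive (a zero numerator carries no fold information
  and is dashed out, matching the tabulation convention of the source
  data);

* the **relative expression coefficient**::

      E_r = TPM_ma / sqrt(TPM_s * TPM_mu)

  the mammary abundance relative to the geometric mean of the two
  reference tissues.  E_r is undefined unless both reference TPMs are
  positive; a zero numerator gives E_r = 0.

Classification uses a twofold rule: a gene is called UP (mammary
upregulated) when ``TPM_ma > TPM_s`` and ``E_r >= 2``, DOWN when
``TPM_ma < TPM_s`` and ``E_r <= 0.5``, and NOT_DIFFERENTIAL otherwise.
Genes with any zero tissue TPM have an incomplete EST profile and are
EXCLUDED from classification.  Thresholds are compared on unrounded
values; rounding is display-only.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from ._util import round_half_away
from .errors import ValidationError
from .model import GeneProfile, StudyTable

__all__ = [
    "Status",
    "ClassifierConfig",
    "ENorthernResult",
    "percent_abundance",
    "ratio_ma_s",
    "relative_expression",
    "classify",
    "stage_preference",
    "run_enorthern",
]


class Status(enum.Enum):
    """Tissue-preference call for one gene."""

    UP = "UP"
    DOWN = "DOWN"
    NOT_DIFFERENTIAL = "NOT_DIFFERENTIAL"
    EXCLUDED = "EXCLUDED"


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds and display precision for the e-Northern classifier.

    up_threshold : minimum E_r (with TPM_ma > TPM_s) to call UP; default 2.
    down_threshold : maximum E_r (with TPM_ma < TPM_s) to call DOWN;
        default 0.5.  Both bounds are inclusive.
    decimals : display rounding for derived columns; never used in
        threshold comparisons.
    """

    up_threshold: float = 2.0
    down_threshold: float = 0.5
    decimals: int = 3

    def __post_init__(self) -> None:
        if not self.up_threshold > 1:
            raise ValidationError("up_threshold must be > 1")
        if not 0 < self.down_threshold < 1:
            raise ValidationError("down_threshold must be in (0, 1)")
        if self.decimals < 0:
            raise ValidationError("decimals must be non-negative")


@dataclass(frozen=True)
class ENorthernResult:
    """Derived statistics and classification for one gene.

    ``pct_abundance``, ``ratio_ma_s`` and ``e_r`` are stored unrounded;
    ``None`` marks an undefined value.
    """

    gene_symbol: str
    profile: GeneProfile
    pct_abundance: float
    ratio_ma_s: float | None
    e_r: float | None
    complete: bool
    status: Status
    adult_preferential: bool | None = None


def percent_abundance(
    table: StudyTable, decimals: int | None = 3
) -> dict[str, float]:
    """Percent mammary transcript abundance for every gene in the table.

    The denominator is the mammary TPM summed over *all* genes, complete
    or not.  ``decimals=None`` returns unrounded values (which sum to
    exactly 100 up to floating-point error).
    """
    total = sum(p.tpm_ma for p in table)
    if total == 0:
        raise ValidationError(
            "mammary TPM column sums to zero: percent abundance undefined"
        )
    out: dict[str, float] = {}
    for p in table:
        pct = 100.0 * p.tpm_ma / total
        out[p.gene_symbol] = pct if decimals is None else round_half_away(pct, decimals)
    return out


def ratio_ma_s(profile: GeneProfile) -> float | None:
    """Mammary/skin TPM ratio, or ``None`` when uninformative.

    Defined only when both TPMs are positive: a zero denominator has no
    ratio, and a zero numerator is dashed out rather than reported as 0.
    """
    if profile.tpm_ma > 0 and profile.tpm_s > 0:
        return profile.tpm_ma / profile.tpm_s
    return None


def relative_expression(profile: GeneProfile) -> float | None:
    """Relative expression coefficient E_r, or ``None`` when undefined.

    E_r = TPM_ma / sqrt(TPM_s * TPM_mu); requires positive skin and muscle
    TPM.  A zero mammary TPM yields E_r = 0.
    """
    if profile.tpm_s > 0 and profile.tpm_mu > 0:
        return profile.tpm_ma / math.sqrt(profile.tpm_s * profile.tpm_mu)
    return None


def classify(
    profile: GeneProfile, config: ClassifierConfig | None = None
) -> Status:
    """Apply the twofold E_r rule to one gene.

    EXCLUDED if any tissue TPM is zero; UP if TPM_ma > TPM_s and
    E_r >= up_threshold; DOWN if TPM_ma < TPM_s and E_r <= down_threshold;
    NOT_DIFFERENTIAL otherwise.  Exactly one status always applies.
    """
    config = config or ClassifierConfig()
    if not profile.complete:
        return Status.EXCLUDED
    e_r = relative_expression(profile)
    assert e_r is not None  # complete implies positive references
    if profile.tpm_ma > profile.tpm_s and e_r >= config.up_threshold:
        return Status.UP
    if profile.tpm_ma < profile.tpm_s and e_r <= config.down_threshold:
        return Status.DOWN
    return Status.NOT_DIFFERENTIAL


def stage_preference(
    profile: GeneProfile, min_fold: float = 1.0
) -> bool | None:
    """Whether expression is adult-preferential.

    ``True`` iff ``tpm_adult > min_fold * tpm_young``; ``None`` when either
    stage TPM is absent.  The default is a strict inequality with no fold
    margin; ties are not preference.
    """
    if profile.tpm_adult is None or profile.tpm_young is None:
        return None
    return profile.tpm_adult > min_fold * profile.tpm_young


def run_enorthern(
    table: StudyTable, config: ClassifierConfig | None = None
) -> list[ENorthernResult]:
    """Full e-Northern pass over a study table, preserving row order."""
    config = config or ClassifierConfig()
    pct = percent_abundance(table, decimals=None)
    results = []
    for p in table:
        results.append(
            ENorthernResult(
                gene_symbol=p.gene_symbol,
                profile=p,
                pct_abundance=pct[p.gene_symbol],
                ratio_ma_s=ratio_ma_s(p),
                e_r=relative_expression(p),
                complete=p.complete,
                status=classify(p, config),
                adult_preferential=stage_preference(p),
            )
        )
    return results
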