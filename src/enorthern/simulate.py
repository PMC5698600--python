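"""Multinomial EST-library simulator with known tissue-preference truth.

An EST library is a fixed-size draw of sequence reads from a tissue's
transcript pool: given true per-gene expression proportions, the gene
counts in a library of size N are multinomial(N, proportions).  TPM is the
count rescaled to a per-million basis, ``round(1e6 * count / N)``, which
reproduces the coarse quantization of real EST-derived TPM values (in a
~34,000-read library every TPM is a multiple of ~29.4).

Tissue-preferential structure is injected through per-gene mammary fold
changes: the mammary proportions are the base proportions multiplied by
the fold and renormalized; skin and muscle sample from the base
proportions.  Truth labels mirror the classifier's twofold convention —
fold >= 2 is a true UP gene, fold <= 0.5 a true DOWN gene, anything else
a null.

Randomness is a single seeded numpy Generator; replicate r uses the
spawned stream ``(seed, r)`` so each replicate is independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from ._util import round_half_away
from .errors import ValidationError
from .model import GeneProfile, StudyTable
from .stats import ENorthernResult, Status

__all__ = ["SimConfig", "SimResult", "RecoveryReport", "simulate", "recovery_report"]

TISSUES = ("mammary", "skin", "muscle")


def _parse_proportions(
    spec: Sequence[float] | str, n_genes: int, rng: np.random.Generator
) -> np.ndarray:
    if isinstance(spec, str):
        if not spec.startswith("dirichlet:"):
            raise ValidationError(f"unknown proportions recipe {spec!r}")
        alpha = float(spec.split(":", 1)[1])
        if alpha <= 0:
            raise ValidationError("dirichlet concentration must be positive")
        return rng.dirichlet(np.full(n_genes, alpha))
    p = np.asarray(spec, dtype=float)
    if p.shape != (n_genes,):
        raise ValidationError(f"expected {n_genes} proportions, got {p.shape}")
    if np.any(p < 0):
        raise ValidationError("proportions must be non-negative")
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValidationError(f"proportions sum to {total}, expected 1")
    return p / total


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated EST-library experiment.

    Parameters
    ----------
    n_genes
        Number of genes in the panel.
    base_proportions
        True expression proportions shared by skin and muscle: a length-
        ``n_genes`` vector summing to 1, or a recipe string
        ``"dirichlet:<alpha>"`` for a symmetric Dirichlet draw.
    fold_changes
        Per-gene mammary fold multipliers (1 = null gene); a vector, or a
        mapping from gene index to fold with default 1.
    library_sizes
        EST reads per tissue library, ``(mammary, skin, muscle)``; default
        34,000 each, the granularity inferred from typical EST-era TPMs.
    seed
        Root seed for the pseudo-random stream.
    """

    n_genes: int
    base_proportions: Sequence[float] | str = "dirichlet:1.0"
    fold_changes: Sequence[float] | Mapping[int, float] = field(
        default_factory=dict
    )
    library_sizes: tuple[int, int, int] = (34_000, 34_000, 34_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if len(self.library_sizes) != 3 or any(
            int(s) < 1 for s in self.library_sizes
        ):
            raise ValidationError("library_sizes must be three positive integers")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        """Load a configuration from a YAML mapping of the field names."""
        with Path(path).open(encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValidationError("simulation config must be a YAML mapping")
        if "library_sizes" in raw:
            raw["library_sizes"] = tuple(int(x) for x in raw["library_sizes"])
        if isinstance(raw.get("fold_changes"), dict):
            raw["fold_changes"] = {
                int(k): float(v) for k, v in raw["fold_changes"].items()
            }
        known = {"n_genes", "base_proportions", "fold_changes", "library_sizes", "seed"}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def fold_vector(self) -> np.ndarray:
        if isinstance(self.fold_changes, Mapping):
            folds = np.ones(self.n_genes)
            for idx, f in self.fold_changes.items():
                if not 0 <= int(idx) < self.n_genes:
                    raise ValidationError(f"fold index {idx} out of range")
                folds[int(idx)] = f
        else:
            folds = np.asarray(self.fold_changes, dtype=float)
            if folds.shape != (self.n_genes,):
                raise ValidationError(
                    f"expected {self.n_genes} fold changes, got {folds.shape}"
                )
        if np.any(folds < 0):
            raise ValidationError("fold changes must be non-negative")
        return folds


@dataclass(frozen=True)
class SimResult:
    """A simulated study table with per-tissue counts and truth labels."""

    table: StudyTable
    truth: dict[str, str]  # gene -> "UP" | "DOWN" | "NULL"
    counts: dict[str, np.ndarray]  # tissue -> per-gene EST counts


def _truth_label(fold: float) -> str:
    if fold >= 2.0:
        return "UP"
    if fold <= 0.5:
        return "DOWN"
    return "NULL"


def simulate(config: SimConfig, replicate: int = 0) -> SimResult:
    """Draw one EST-library experiment.

    Deterministic given ``(config.seed, replicate)``.  Per tissue, gene
    counts are a single multinomial draw at that tissue's library size, so
    counts sum exactly to the library size; TPMs are the counts scaled to
    a million and rounded half-away-from-zero to integers.
    """
    rng = np.random.default_rng([int(config.seed), int(replicate)])
    base = _parse_proportions(config.base_proportions, config.n_genes, rng)
    folds = config.fold_vector()

    p_ma = base * folds
    total = p_ma.sum()
    if total <= 0:
        raise ValidationError("mammary proportions are identically zero")
    p_ma = p_ma / total

    libs = tuple(int(s) for s in config.library_sizes)
    props = {"mammary": p_ma, "skin": base, "muscle": base}
    counts = {
        tissue: rng.multinomial(libs[i], props[tissue])
        for i, tissue in enumerate(TISSUES)
    }

    def tpm(tissue: str, i: int) -> int:
        lib = libs[TISSUES.index(tissue)]
        return int(round_half_away(1e6 * counts[tissue][i] / lib, 0))

    width = len(str(config.n_genes))
    profiles = []
    truth: dict[str, str] = {}
    for i in range(config.n_genes):
        gene = f"G{i + 1:0{width}d}"
        profiles.append(
            GeneProfile(
                gene_symbol=gene,
                tpm_ma=tpm("mammary", i),
                tpm_s=tpm("skin", i),
                tpm_mu=tpm("muscle", i),
                bioprocess="simulated",
            )
        )
        truth[gene] = _truth_label(folds[i])
    table = StudyTable(profiles, source_label=f"simulated(seed={config.seed}, r={replicate})")
    return SimResult(table=table, truth=truth, counts=counts)


@dataclass(frozen=True)
class RecoveryReport:
    """Confusion of simulated truth against classifier calls.

    ``confusion[truth][status]`` counts genes; EXCLUDED is a status column
    of its own, so exclusions are tracked, not conflated with miscalls.
    Sensitivity for class c is the fraction of truth-c genes called c;
    specificity the fraction of non-c genes not called c (UP/DOWN map to
    their statuses, NULL to NOT_DIFFERENTIAL).
    """

    confusion: dict[str, dict[str, int]]
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    n_excluded: int

    def to_text(self) -> str:
        statuses = [s.name for s in Status]
        lines = ["truth\\status\t" + "\t".join(statuses)]
        for t in ("UP", "DOWN", "NULL"):
            lines.append(
                t + "\t" + "\t".join(str(self.confusion[t][s]) for s in statuses)
            )
        lines.append("")
        for t in ("UP", "DOWN", "NULL"):
            sens = self.sensitivity[t]
            spec = self.specificity[t]
            lines.append(
                f"{t}: sensitivity="
                + ("nan" if np.isnan(sens) else f"{sens:.4f}")
                + " specificity="
                + ("nan" if np.isnan(spec) else f"{spec:.4f}")
            )
        lines.append(f"excluded: {self.n_excluded}")
        return "\n".join(lines)


_TRUTH_TO_STATUS = {
    "UP": Status.UP,
    "DOWN": Status.DOWN,
    "NULL": Status.NOT_DIFFERENTIAL,
}


def recovery_report(
    sim: SimResult, results: Sequence[ENorthernResult]
) -> RecoveryReport:
    """Score classifier output against the simulator's truth labels."""
    by_gene = {r.gene_symbol: r for r in results}
    if set(by_gene) != set(sim.truth):
        raise ValidationError("result genes do not match simulated genes")

    statuses = [s.name for s in Status]
    confusion = {t: {s: 0 for s in statuses} for t in ("UP", "DOWN", "NULL")}
    for gene, t in sim.truth.items():
        confusion[t][by_gene[gene].status.name] += 1

    sensitivity: dict[str, float] = {}
    specificity: dict[str, float] = {}
    for t, target in _TRUTH_TO_STATUS.items():
        pos = sum(confusion[t].values())
        hit = confusion[t][target.name]
        sensitivity[t] = hit / pos if pos else float("nan")
        neg = sum(
            confusion[other][s]
            for other in confusion
            if other != t
            for s in statuses
        )
        false_pos = sum(
            confusion[other][target.name] for other in confusion if other != t
        )
        specificity[t] = (neg - false_pos) / neg if neg else float("nan")

    n_excluded = sum(confusion[t]["EXCLUDED"] for t in confusion)
    return RecoveryReport(
        confusion=confusion,
        sensitivity=sensitivity,
        specificity=specificity,
        n_excluded=n_excluded,
    )
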