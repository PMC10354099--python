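"""Core in-memory containers shared by every stage of the pipeline.

Gene and sample identifiers are opaque, case-sensitive strings; no symbol
aliasing or probe mapping happens anywhere in the package.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

Modality = Literal["bulk", "single_cell"]


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix.

    Bulk values are expected on a log scale (finite floats); single-cell
    values are raw non-negative counts.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    modality: Modality = "bulk"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        ng, ns = len(self.gene_ids), len(self.sample_ids)
        if self.values.shape != (ng, ns):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{ng} genes x {ns} samples"
            )
        if len(set(self.gene_ids)) != ng:
            raise ValidationError("duplicate gene ids")
        if len(set(self.sample_ids)) != ns:
            raise ValidationError("duplicate sample ids")
        if self.modality == "bulk":
            if not np.all(np.isfinite(self.values)):
                raise ValidationError("bulk expression values must be finite")
        elif self.modality == "single_cell":
            if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
                raise ValidationError("single-cell counts must be finite and >= 0")
        else:
            raise ValidationError(f"unknown modality {self.modality!r}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, modality: Modality = "bulk") -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in df.index],
            sample_ids=[str(s) for s in df.columns],
            values=df.to_numpy(dtype=float),
            modality=modality,
        )

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in idx]
        if missing:
            raise KeyError(f"unknown samples: {missing}")
        cols = [idx[s] for s in samples]
        return dataclasses.replace(
            self, sample_ids=list(samples), values=self.values[:, cols]
        )


@dataclass
class GeneSetCollection:
    """Named gene lists (TF target sets, marker sets or signatures)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    category: Literal["tf_targets", "cell_markers", "signature"] = "signature"

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"gene set {name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    @property
    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class SurvivalTable:
    """Per-patient follow-up: time on a single consistent unit, event flag."""

    patient_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    group: list[str] | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = len(self.patient_ids)
        if len(set(self.patient_ids)) != n:
            raise ValidationError("duplicate patient ids")
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValidationError("time/event length mismatch")
        if np.any(self.time < 0):
            raise ValidationError("negative survival times")
        if not np.all(np.isin(self.event, (0, 1))):
            raise ValidationError("event indicator must be 0 or 1")
        if self.group is not None and len(self.group) != n:
            raise ValidationError("group label length mismatch")

    def __len__(self) -> int:
        return len(self.patient_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"patient_id": self.patient_ids, "time": self.time, "event": self.event}
        )
        if self.group is not None:
            df["group"] = self.group
        return df


@dataclass
class DilutionAssay:
    """Limiting-dilution plate table: wells challenged per cell dose."""

    group: list[str]
    dose: np.ndarray
    n_tested: np.ndarray
    n_response: np.ndarray

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        self.n_tested = np.asarray(self.n_tested, dtype=int)
        self.n_response = np.asarray(self.n_response, dtype=int)
        n = len(self.group)
        if not (self.dose.shape == self.n_tested.shape == self.n_response.shape == (n,)):
            raise ValidationError("dilution table column length mismatch")
        if n == 0:
            raise ValidationError("empty dilution table")
        if np.any(self.dose <= 0):
            raise ValidationError("doses must be > 0")
        if np.any(self.n_tested <= 0):
            raise ValidationError("n_tested must be positive")
        if np.any(self.n_response < 0) or np.any(self.n_response > self.n_tested):
            raise ValidationError("response exceeds tested")

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.group:
            seen.setdefault(g, None)
        return list(seen)

    def rows_for(self, group: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        mask = np.array([g == group for g in self.group])
        if not mask.any():
            raise KeyError(f"unknown group {group!r}")
        return self.dose[mask], self.n_tested[mask], self.n_response[mask]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "dose": self.dose,
                "tested": self.n_tested,
                "response": self.n_response,
            }
        )
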