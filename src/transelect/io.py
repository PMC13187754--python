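"""Domain types and plain-text I/O for transaminase screening data.

The experimental unit is one micro-scale reaction: a prochiral ketone substrate
crossed with one commercial transaminase, read out as UV conversion (percent)
and, where measurable, enantiomeric excess (percent).  ee is stored as an
unsigned magnitude in [0, 100]; the enantiomer identity is carried by the
enzyme's selectivity class (S or R).  Diastereomeric ratios are ingested
through the same column as "de" — the workflow treats them identically.

All files are plain text: CSV (comma, UTF-8, header required, "." decimal),
concatenated XYZ for conformer ensembles, YAML for run configuration.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml


class SchemaError(ValueError):
    """A file is missing required columns or has a malformed layout."""


class ValidationError(ValueError):
    """A record violates a domain invariant (e.g. conversion outside [0,100])."""


class FormatError(ValueError):
    """A structured text block (XYZ, ...) could not be parsed."""


EE_MISSING_REASONS = ("measured", "low_conversion", "analytical_failure", "not_applicable")

#: Canonical featurization tags (the five substrate representations), plus
#: "synthetic" for generator output.
FEATURIZATION_TAGS = ("OHE", "fp", "phys", "DFT", "phys+DFT", "synthetic")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnzymeEntry:
    enzyme_id: str
    selectivity_class: str  # "S" or "R"
    vendor: str | None = None

    def __post_init__(self) -> None:
        if self.selectivity_class not in ("S", "R"):
            raise ValidationError(
                f"enzyme {self.enzyme_id!r}: selectivity_class must be 'S' or 'R', "
                f"got {self.selectivity_class!r}"
            )


@dataclass(frozen=True)
class EnzymePanel:
    """The fixed set of candidate enzymes, each with a typical S/R selectivity."""

    entries: tuple[EnzymeEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.enzyme_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValidationError("enzyme_ids in a panel must be unique")

    @property
    def enzyme_ids(self) -> list[str]:
        return [e.enzyme_id for e in self.entries]

    def selectivity_class(self, enzyme_id: str) -> str:
        for e in self.entries:
            if e.enzyme_id == enzyme_id:
                return e.selectivity_class
        raise KeyError(enzyme_id)

    def subset(self, selectivity_class: str) -> "EnzymePanel":
        kept = tuple(e for e in self.entries if e.selectivity_class == selectivity_class)
        return EnzymePanel(kept)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ReactionOutcome:
    """One substrate x enzyme reaction; ee may be unmeasured (None)."""

    substrate_id: str
    enzyme_id: str
    conversion: float          # percent, [0, 100]
    ee: float | None = None    # percent, [0, 100], None = MISSING
    ee_missing_reason: str = "measured"

    def __post_init__(self) -> None:
        if not np.isfinite(self.conversion) or not 0.0 <= self.conversion <= 100.0:
            raise ValidationError(
                f"reaction ({self.substrate_id}, {self.enzyme_id}): conversion "
                f"{self.conversion!r} outside [0, 100]"
            )
        if self.ee is not None and not 0.0 <= self.ee <= 100.0:
            raise ValidationError(
                f"reaction ({self.substrate_id}, {self.enzyme_id}): ee {self.ee!r} "
                "outside [0, 100]"
            )
        if self.ee_missing_reason not in EE_MISSING_REASONS:
            raise ValidationError(
                f"unknown ee_missing_reason {self.ee_missing_reason!r}"
            )
        if self.ee is None and self.ee_missing_reason == "measured":
            object.__setattr__(self, "ee_missing_reason", "analytical_failure")

    @property
    def ee_measured(self) -> bool:
        return self.ee is not None


@dataclass(frozen=True)
class SubstrateRecord:
    """A ketone substrate: SMILES plus the reaction-site atom indices.

    ``carbonyl_atom_index`` and ``alpha_atom_indices`` refer to the atom
    ordering of the 3D geometry used for steric descriptors (which need not
    be RDKit's SMILES atom order).
    """

    substrate_id: str
    smiles: str
    ketone_class: str = ""
    carbonyl_atom_index: int | None = None
    alpha_atom_indices: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        from rdkit import Chem

        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise ValidationError(
                f"substrate {self.substrate_id!r}: SMILES {self.smiles!r} does not parse"
            )
        if not mol.HasSubstructMatch(Chem.MolFromSmarts("[#6][CX3](=O)[#6]")):
            raise ValidationError(
                f"substrate {self.substrate_id!r}: SMILES {self.smiles!r} contains "
                "no ketone carbonyl"
            )


@dataclass(frozen=True)
class ConformerEnsemble:
    """Conformers of one substrate with energies relative to the minimum.

    Energies are kcal/mol, re-referenced so the ensemble minimum is exactly 0;
    all conformers share one atom count and ordering.
    """

    substrate_id: str
    elements: tuple[str, ...]
    coordinates: tuple[np.ndarray, ...]   # each (n_atoms, 3), angstrom
    energies: tuple[float, ...]           # kcal/mol relative to minimum

    MAX_CONFORMERS = 20

    def __post_init__(self) -> None:
        n = len(self.coordinates)
        if not 1 <= n <= self.MAX_CONFORMERS:
            raise ValidationError(
                f"ensemble {self.substrate_id!r}: {n} conformers outside "
                f"[1, {self.MAX_CONFORMERS}]"
            )
        if len(self.energies) != n:
            raise ValidationError("one energy per conformer required")
        for c in self.coordinates:
            if c.shape != (len(self.elements), 3):
                raise ValidationError(
                    f"ensemble {self.substrate_id!r}: conformer shape {c.shape} does "
                    f"not match {len(self.elements)} atoms"
                )
        if abs(min(self.energies)) > 1e-9:
            raise ValidationError("relative energies must have minimum 0")

    def __len__(self) -> int:
        return len(self.coordinates)


@dataclass(frozen=True)
class FeatureTable:
    """Substrate-by-descriptor numeric matrix with a featurization tag."""

    df: pd.DataFrame            # index: substrate_id, columns: feature names
    tag: str

    def __post_init__(self) -> None:
        if self.tag not in FEATURIZATION_TAGS:
            raise ValidationError(
                f"unknown featurization tag {self.tag!r}; expected one of "
                f"{FEATURIZATION_TAGS}"
            )
        if self.df.columns.duplicated().any():
            raise ValidationError("feature names must be unique")
        if self.df.index.duplicated().any():
            raise ValidationError("substrate ids must be unique")
        if not np.all(np.isfinite(self.df.to_numpy(dtype=float))):
            raise ValidationError("feature table contains NaN/Inf after assembly")

    @property
    def substrate_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    def row(self, substrate_id: str) -> pd.Series:
        return self.df.loc[substrate_id]

    @staticmethod
    def concat(left: "FeatureTable", right: "FeatureTable", tag: str) -> "FeatureTable":
        """Column-concatenate two tables over the same substrates (e.g. phys+DFT)."""
        if list(left.df.index) != list(right.df.index):
            raise ValidationError("tables must cover the same substrates in order")
        return FeatureTable(pd.concat([left.df, right.df], axis=1), tag)


@dataclass
class RunConfig:
    """Workflow-level knobs.

    conversion_threshold: percent conversion above which a reaction counts as a
        success (strict ">"), the gate and outcome rules both use it.
    temperature_reaction: K, used for the ee <-> DDG transform (reaction run at
        35 C).
    temperature_boltzmann: K, used for conformer population weighting.
    tie_tolerance: percent ee within which enzymes count as co-best.
    """

    conversion_threshold: float = 25.0
    temperature_reaction: float = 308.15
    temperature_boltzmann: float = 298.15
    tie_tolerance: float = 0.0
    fp_radius: int = 2
    fp_bits: int = 2048
    rf_trees: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.conversion_threshold <= 0:
            raise ValidationError("conversion_threshold must be > 0")
        if self.temperature_reaction <= 0 or self.temperature_boltzmann <= 0:
            raise ValidationError("temperatures must be > 0 K")
        if self.tie_tolerance < 0:
            raise ValidationError("tie_tolerance must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_REACTION_COLUMNS = ["substrate_id", "enzyme_id", "conversion_pct", "ee_pct"]


def read_reaction_table(path: str | Path) -> list[ReactionOutcome]:
    """Read reactions.csv; a blank ee field is MISSING, never coerced to 0."""
    df = pd.read_csv(
        path,
        dtype={"substrate_id": str, "enzyme_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in _REACTION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    has_reason = "ee_missing_reason" in df.columns
    records: list[ReactionOutcome] = []
    for i, row in df.iterrows():
        conversion = float(row["conversion_pct"])
        if not np.isfinite(conversion) or not 0.0 <= conversion <= 100.0:
            raise ValidationError(
                f"{path} row {i + 2}: conversion {row['conversion_pct']!r} outside [0, 100]"
            )
        ee = None if pd.isna(row["ee_pct"]) else float(row["ee_pct"])
        reason = "measured" if ee is not None else "analytical_failure"
        if has_reason and not pd.isna(row["ee_missing_reason"]):
            reason = str(row["ee_missing_reason"])
        records.append(
            ReactionOutcome(
                substrate_id=str(row["substrate_id"]),
                enzyme_id=str(row["enzyme_id"]),
                conversion=conversion,
                ee=ee,
                ee_missing_reason=reason,
            )
        )
    return records


def write_reaction_table(records: Iterable[ReactionOutcome], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_REACTION_COLUMNS + ["ee_missing_reason"])
        for r in records:
            writer.writerow(
                [
                    r.substrate_id,
                    r.enzyme_id,
                    repr(r.conversion),
                    "" if r.ee is None else repr(r.ee),
                    r.ee_missing_reason,
                ]
            )


def read_panel(path: str | Path) -> EnzymePanel:
    """Read panel.csv with columns enzyme_id, selectivity_class[, vendor]."""
    df = pd.read_csv(path, dtype=str)
    for col in ("enzyme_id", "selectivity_class"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    entries = tuple(
        EnzymeEntry(
            enzyme_id=row["enzyme_id"],
            selectivity_class=row["selectivity_class"],
            vendor=row.get("vendor") if isinstance(row.get("vendor"), str) else None,
        )
        for _, row in df.iterrows()
    )
    return EnzymePanel(entries)


def write_panel(panel: EnzymePanel, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["enzyme_id", "selectivity_class", "vendor"])
        for e in panel.entries:
            writer.writerow([e.enzyme_id, e.selectivity_class, e.vendor or ""])


def read_conformer_xyz(path: str | Path, substrate_id: str | None = None) -> ConformerEnsemble:
    """Read a concatenated-XYZ conformer ensemble.

    Each block: atom count line, comment line carrying the energy as a labelled
    token ``E=<value>`` (kcal/mol, any reference), then one line per atom.
    Energies are re-referenced so the ensemble minimum is 0.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    blocks: list[tuple[float, list[str], np.ndarray]] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise FormatError(f"{path}: expected atom count at line {i + 1}")
        if i + 1 + natoms >= len(lines) + 1 and natoms > 0:
            raise FormatError(f"{path}: truncated XYZ block at line {i + 1}")
        comment = lines[i + 1]
        energy = None
        for token in comment.replace(",", " ").split():
            if token.startswith("E="):
                try:
                    energy = float(token[2:])
                except ValueError:
                    raise FormatError(f"{path}: unparseable energy token {token!r}")
        if energy is None:
            raise FormatError(f"{path}: no 'E=<value>' token on comment line {i + 2}")
        elements: list[str] = []
        coords = np.empty((natoms, 3))
        for j in range(natoms):
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                raise FormatError(f"{path}: malformed atom line {i + 3 + j}")
            elements.append(parts[0])
            coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
        blocks.append((energy, elements, coords))
        i += 2 + natoms
    if not blocks:
        raise FormatError(f"{path}: no XYZ blocks found")
    ref_elements = blocks[0][1]
    for energy, elements, _ in blocks:
        if elements != ref_elements:
            raise FormatError(
                f"{path}: conformers differ in atom count/ordering "
                f"({len(elements)} vs {len(ref_elements)} atoms)"
            )
    emin = min(b[0] for b in blocks)
    return ConformerEnsemble(
        substrate_id=substrate_id or path.stem,
        elements=tuple(ref_elements),
        coordinates=tuple(b[2] for b in blocks),
        energies=tuple(b[0] - emin for b in blocks),
    )


def write_conformer_xyz(ensemble: ConformerEnsemble, path: str | Path) -> None:
    with open(path, "w") as fh:
        for coords, energy in zip(ensemble.coordinates, ensemble.energies):
            fh.write(f"{len(ensemble.elements)}\n")
            fh.write(f"{ensemble.substrate_id} E={energy:.8f}\n")
            for el, (x, y, z) in zip(ensemble.elements, coords):
                fh.write(f"{el} {x:.8f} {y:.8f} {z:.8f}\n")


@dataclass(frozen=True)
class QMFeatures:
    """Per-substrate quantum-chemical descriptors, already Boltzmann-averaged
    upstream: molecule-level values plus atom-level values keyed by atom index."""

    molecule: Mapping[str, float]
    atoms: Mapping[int, Mapping[str, float]]


def read_qm_feature_table(path: str | Path) -> dict[str, QMFeatures]:
    """Read qm_features.csv: substrate_id, level (molecule|atom), atom_index,
    feature_name, value.  Names are preserved verbatim."""
    df = pd.read_csv(path, dtype={"substrate_id": str, "feature_name": str})
    for col in ("substrate_id", "level", "feature_name", "value"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    key_cols = ["substrate_id", "level", "atom_index", "feature_name"]
    if "atom_index" not in df.columns:
        df["atom_index"] = np.nan
    if df.duplicated(subset=key_cols).any():
        dup = df[df.duplicated(subset=key_cols, keep=False)].iloc[0]
        raise ValidationError(
            f"{path}: duplicate feature row for substrate {dup['substrate_id']!r}, "
            f"feature {dup['feature_name']!r}"
        )
    out: dict[str, QMFeatures] = {}
    for sid, group in df.groupby("substrate_id", sort=False):
        molecule: dict[str, float] = {}
        atoms: dict[int, dict[str, float]] = {}
        for _, row in group.iterrows():
            level = str(row["level"])
            if level == "molecule":
                molecule[row["feature_name"]] = float(row["value"])
            elif level == "atom":
                if pd.isna(row["atom_index"]):
                    raise ValidationError(
                        f"{path}: atom-level row for {sid!r} without atom_index"
                    )
                atoms.setdefault(int(row["atom_index"]), {})[row["feature_name"]] = float(
                    row["value"]
                )
            else:
                raise ValidationError(f"{path}: unknown level {level!r}")
        out[str(sid)] = QMFeatures(molecule=molecule, atoms=atoms)
    return out


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write features as CSV with the featurization tag in a sidecar YAML."""
    path = Path(path)
    table.df.to_csv(path, index_label="substrate_id")
    sidecar = path.with_suffix(path.suffix + ".meta.yaml")
    sidecar.write_text(yaml.safe_dump({"featurization_tag": table.tag}))


def read_feature_table(path: str | Path, tag: str | None = None) -> FeatureTable:
    path = Path(path)
    df = pd.read_csv(path, index_col="substrate_id")
    df.index = df.index.astype(str)
    if tag is None:
        sidecar = path.with_suffix(path.suffix + ".meta.yaml")
        if sidecar.exists():
            tag = yaml.safe_load(sidecar.read_text())["featurization_tag"]
        else:
            tag = "synthetic"
            warnings.warn(f"{path}: no sidecar metadata; assuming tag 'synthetic'")
    return FeatureTable(df, tag)


def full_factorial_complete(records: Sequence[ReactionOutcome]) -> bool:
    """True iff records form one full substrate x enzyme grid (no holes, no dupes)."""
    pairs = {(r.substrate_id, r.enzyme_id) for r in records}
    subs = {r.substrate_id for r in records}
    enzs = {r.enzyme_id for r in records}
    return len(pairs) == len(records) == len(subs) * len(enzs)
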