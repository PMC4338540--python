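"""Cohort data model, TSV readers/writers and sample alignment.

A cohort is a set of tables keyed by sample ID: a log-scale expression
matrix (genes x samples), a binary lesion matrix (samples x lesions, each
lesion labelled ``genetic`` or ``cytogenetic``), a clinical table of blood
and bone-marrow variables with declared value domains, demographics (sex,
age) and right-censored survival.  Tables are aligned to the sorted
intersection of their sample IDs; missing clinical values stay missing
(encoded as ``NA`` on disk) and are handled complete-case per model, never
imputed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: value domains a clinical variable may declare
CLINICAL_DOMAINS = ("real", "positive", "unit-interval", "binary")

LESION_CLASSES = ("genetic", "cytogenetic")

NA_REP = "NA"
FLOAT_FMT = "%.6g"


class CohortFormatError(ValueError):
    """A cohort file is malformed (missing column, bad header)."""


class CohortValidationError(ValueError):
    """A cohort table violates a declared invariant (domain, binarity)."""


def _check_unique(ids, what: str) -> None:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if list(ids).count(i) > 1})
        raise CohortValidationError(f"duplicate {what} identifiers: {dup[:5]}")


@dataclass
class ExpressionMatrix:
    """Log2-scale expression, genes x samples."""

    values: pd.DataFrame  # index=genes, columns=samples

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise CohortValidationError("expression matrix contains non-finite values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class LesionMatrix:
    """Binary lesion calls, samples x lesions, with per-lesion class labels."""

    values: pd.DataFrame  # index=samples, columns=lesions, entries 0/1
    classes: dict[str, str] = field(default_factory=dict)  # lesion -> class

    def __post_init__(self) -> None:
        _check_unique(self.values.columns, "lesion")
        _check_unique(self.values.index, "sample")
        arr = self.values.to_numpy(dtype=float)
        if not np.isin(arr, (0.0, 1.0)).all():
            bad = sorted(set(arr.ravel()) - {0.0, 1.0})
            raise CohortValidationError(f"lesion matrix entries must be 0/1, found {bad[:5]}")
        for lesion in self.values.columns:
            cls = self.classes.get(lesion)
            if cls not in LESION_CLASSES:
                raise CohortValidationError(
                    f"lesion {lesion!r} has class {cls!r}; expected one of {LESION_CLASSES}"
                )

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def lesions(self) -> list[str]:
        return list(self.values.columns)

    def lesions_of_class(self, cls: str) -> list[str]:
        return [l for l in self.lesions if self.classes[l] == cls]


@dataclass
class ClinicalTable:
    """Clinical phenotypes with declared value domains; NaN marks missing."""

    values: pd.DataFrame  # index=samples, columns=variables
    domains: dict[str, str] = field(default_factory=dict)  # variable -> domain
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "sample")
        _check_unique(self.values.columns, "variable")
        for var in self.values.columns:
            dom = self.domains.get(var)
            if dom not in CLINICAL_DOMAINS:
                raise CohortValidationError(
                    f"clinical variable {var!r} has domain {dom!r}; expected one of {CLINICAL_DOMAINS}"
                )
            obs = self.values[var].dropna().to_numpy(dtype=float)
            if dom == "positive" and (obs <= 0).any():
                raise CohortValidationError(f"variable {var!r} declared positive has values <= 0")
            if dom == "unit-interval" and ((obs < 0) | (obs > 1)).any():
                raise CohortValidationError(f"variable {var!r} declared unit-interval outside [0,1]")
            if dom == "binary" and not np.isin(obs, (0.0, 1.0)).all():
                raise CohortValidationError(f"variable {var!r} declared binary is not 0/1")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SurvivalTable:
    """Right-censored survival: time in days, status 1 = event."""

    values: pd.DataFrame  # index=samples, columns=[time_days, status]

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "sample")
        for col in ("time_days", "status"):
            if col not in self.values.columns:
                raise CohortFormatError(f"survival table missing column {col!r}")
        t = self.values["time_days"].to_numpy(dtype=float)
        s = self.values["status"].to_numpy(dtype=float)
        if not np.isin(s[~np.isnan(s)], (0.0, 1.0)).all():
            raise CohortValidationError("survival status must be 0/1")
        finite_t = t[~np.isnan(t)]
        if finite_t.size and finite_t.min() < 0:
            raise CohortValidationError("survival time must be >= 0")
        if np.isnan(t[s == 1.0]).any():
            raise CohortValidationError("event (status=1) with missing time")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def time(self) -> np.ndarray:
        return self.values["time_days"].to_numpy(dtype=float)

    @property
    def status(self) -> np.ndarray:
        return self.values["status"].to_numpy(dtype=float)


@dataclass
class CohortBundle:
    """All cohort tables aligned to one ordered sample list."""

    expression: ExpressionMatrix
    lesions: LesionMatrix
    clinical: ClinicalTable
    demographics: pd.DataFrame  # index=samples, columns=[sex, age]; sex 1=female
    survival: SurvivalTable
    normal_flag: pd.Series  # index=samples, 1 = healthy control

    @property
    def samples(self) -> list[str]:
        return list(self.expression.samples)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def validate(self) -> None:
        ref = self.samples
        for name, got in (
            ("lesions", self.lesions.samples),
            ("clinical", self.clinical.samples),
            ("demographics", list(self.demographics.index)),
            ("survival", self.survival.samples),
            ("normal_flag", list(self.normal_flag.index)),
        ):
            if got != ref:
                raise CohortValidationError(f"{name} sample order differs from expression")
        normals = self.normal_flag.to_numpy(dtype=float) == 1.0
        if normals.any():
            rows = self.lesions.values.to_numpy(dtype=float)[normals]
            if rows.any():
                raise CohortValidationError("normal control with nonzero lesion row")


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path: Path, index_col: int = 0, comment: str | None = "#") -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=index_col, comment=comment,
                         na_values=[NA_REP], keep_default_na=False)
    except FileNotFoundError:
        raise CohortFormatError(f"cohort file not found: {path}")
    df.index = df.index.astype(str)
    return df


def read_expression(path: str | Path) -> ExpressionMatrix:
    return ExpressionMatrix(_read_tsv(Path(path)))


def read_lesions(path: str | Path) -> LesionMatrix:
    """Read samples x lesions 0/1 TSV with a ``#classes`` metadata line.

    The first line of the file must be ``#classes<TAB>cls1<TAB>cls2...``
    assigning each lesion column to ``genetic`` or ``cytogenetic``.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
    if not first.startswith("#classes"):
        raise CohortFormatError(f"{path}: expected '#classes' metadata line as first line")
    class_fields = first.split("\t")[1:]
    df = _read_tsv(path)
    if len(class_fields) != df.shape[1]:
        raise CohortFormatError(
            f"{path}: #classes line has {len(class_fields)} entries for {df.shape[1]} lesions"
        )
    classes = dict(zip(df.columns, class_fields))
    return LesionMatrix(df, classes)


def read_clinical(path: str | Path, spec_path: str | Path) -> ClinicalTable:
    """Read clinical TSV plus a companion spec declaring column domains.

    The spec is a TSV with columns ``variable``, ``domain`` and optional
    ``units``.
    """
    df = _read_tsv(Path(path))
    spec = pd.read_csv(spec_path, sep="\t")
    for col in ("variable", "domain"):
        if col not in spec.columns:
            raise CohortFormatError(f"{spec_path}: missing required column {col!r}")
    domains = dict(zip(spec["variable"], spec["domain"]))
    units = dict(zip(spec["variable"], spec.get("units", [""] * len(spec))))
    missing = [v for v in df.columns if v not in domains]
    if missing:
        raise CohortFormatError(f"{spec_path}: no domain declared for variables {missing}")
    return ClinicalTable(df, domains, units)


def read_survival(path: str | Path) -> SurvivalTable:
    df = _read_tsv(Path(path))
    return SurvivalTable(df)


def read_demographics(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    df = _read_tsv(Path(path))
    for col in ("sex", "age", "normal"):
        if col not in df.columns:
            raise CohortFormatError(f"{path}: missing required column {col!r}")
    return df[["sex", "age"]], df["normal"]


def load_cohort(paths: dict[str, str | Path]) -> CohortBundle:
    """Load and align all cohort tables from TSV files.

    Parameters
    ----------
    paths
        Mapping with keys ``expression``, ``lesions``, ``clinical``,
        ``clinical_spec``, ``demographics``, ``survival``.

    The returned bundle's sample list is the sorted intersection of the
    per-table sample sets; dropped-sample counts are logged per table.
    """
    required = ("expression", "lesions", "clinical", "clinical_spec", "demographics", "survival")
    for key in required:
        if key not in paths:
            raise CohortFormatError(f"load_cohort: missing path for {key!r}")
    expr = read_expression(paths["expression"])
    lesions = read_lesions(paths["lesions"])
    clinical = read_clinical(paths["clinical"], paths["clinical_spec"])
    demo, normal = read_demographics(paths["demographics"])
    surv = read_survival(paths["survival"])

    tables = {
        "expression": set(expr.samples),
        "lesions": set(lesions.samples),
        "clinical": set(clinical.samples),
        "demographics": set(demo.index),
        "survival": set(surv.samples),
    }
    common = sorted(set.intersection(*tables.values()))
    if not common:
        raise CohortValidationError("sample intersection across cohort tables is empty")
    for name, ids in tables.items():
        dropped = len(ids) - len(common)
        if dropped:
            logger.info("load_cohort: dropped %d sample(s) from %s", dropped, name)

    bundle = CohortBundle(
        expression=ExpressionMatrix(expr.values.loc[:, common]),
        lesions=LesionMatrix(lesions.values.loc[common], lesions.classes),
        clinical=ClinicalTable(clinical.values.loc[common], clinical.domains, clinical.units),
        demographics=demo.loc[common],
        survival=SurvivalTable(surv.values.loc[common]),
        normal_flag=normal.loc[common],
    )
    bundle.validate()
    return bundle


_ANALYSES = ("deconvolution", "phenotypes", "survival", "pca")


def align_and_mask(bundle: CohortBundle, analysis: str) -> pd.Series:
    """Boolean mask of samples with complete required data for one analysis.

    ``pca`` needs expression only; ``deconvolution`` additionally requires
    complete lesion and demographic data; ``survival`` additionally a
    non-missing survival time; ``phenotypes`` is like deconvolution
    (complete-case filtering per phenotype happens inside the phenotype
    models, not here).
    """
    if analysis not in _ANALYSES:
        raise ValueError(f"unknown analysis {analysis!r}; expected one of {_ANALYSES}")
    mask = pd.Series(True, index=bundle.samples)
    if analysis == "pca":
        pass
    else:
        mask &= bundle.lesions.values.notna().all(axis=1)
        mask &= bundle.demographics[["sex", "age"]].notna().all(axis=1)
        if analysis == "survival":
            sv = bundle.survival.values
            mask &= sv["time_days"].notna() & sv["status"].notna()
    if not mask.any():
        raise CohortValidationError(f"no sample has complete data for analysis {analysis!r}")
    return mask


def subset_bundle(bundle: CohortBundle, samples: list[str]) -> CohortBundle:
    """Restrict a bundle to a sample subset, preserving the given order."""
    out = CohortBundle(
        expression=ExpressionMatrix(bundle.expression.values.loc[:, samples]),
        lesions=LesionMatrix(bundle.lesions.values.loc[samples], bundle.lesions.classes),
        clinical=ClinicalTable(bundle.clinical.values.loc[samples],
                               bundle.clinical.domains, bundle.clinical.units),
        demographics=bundle.demographics.loc[samples],
        survival=SurvivalTable(bundle.survival.values.loc[samples]),
        normal_flag=bundle.normal_flag.loc[samples],
    )
    out.validate()
    return out


def write_tsv(df: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    """Write a deterministic TSV: fixed column order, %.6g floats, NA markers."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", na_rep=NA_REP, float_format=FLOAT_FMT, index_label=index_label)


def write_cohort(bundle: CohortBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle as the standard cohort TSVs; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    p = out / "expression.tsv"
    write_tsv(bundle.expression.values, p, index_label="gene")
    paths["expression"] = p

    p = out / "lesions.tsv"
    with open(p, "w") as fh:
        fh.write("#classes\t" + "\t".join(bundle.lesions.classes[l] for l in bundle.lesions.lesions) + "\n")
        bundle.lesions.values.astype(int).to_csv(fh, sep="\t", index_label="sample")
    paths["lesions"] = p

    p = out / "clinical.tsv"
    write_tsv(bundle.clinical.values, p, index_label="sample")
    paths["clinical"] = p

    p = out / "clinical_spec.tsv"
    spec = pd.DataFrame({
        "variable": bundle.clinical.variables,
        "domain": [bundle.clinical.domains[v] for v in bundle.clinical.variables],
        "units": [bundle.clinical.units.get(v, "") for v in bundle.clinical.variables],
    })
    spec.to_csv(p, sep="\t", index=False)
    paths["clinical_spec"] = p

    p = out / "demographics.tsv"
    demo = bundle.demographics.copy()
    demo["normal"] = bundle.normal_flag
    write_tsv(demo, p, index_label="sample")
    paths["demographics"] = p

    p = out / "survival.tsv"
    write_tsv(bundle.survival.values, p, index_label="sample")
    paths["survival"] = p
    return paths


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(out_dir: str | Path, config: dict, seed: int,
                   inputs: dict[str, str | Path] | None = None) -> Path:
    """Write a machine-readable run manifest (config, seed, input checksums)."""
    manifest = {
        "config": config,
        "seed": int(seed),
        "input_checksums": {k: file_checksum(v) for k, v in (inputs or {}).items()},
    }
    path = Path(out_dir) / "manifest.json"
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
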