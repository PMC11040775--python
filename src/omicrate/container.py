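"""Versioned on-disk study containers and a local registry.

A container is a plain directory (zip for export) — portable, language
neutral and diff-able:

.. code-block:: text

    <study-name>/
      manifest.json                 schema version, study fields, inventory
                                    with per-file SHA-256 checksums, history
      metadata.json                 open metadata, per-model/test descriptions,
                                    column metadata, plot-hook registry
      linkouts.json
      results/<model>/<test>.tsv
      assays/<model>/matrix.tsv     features x samples
      assays/<model>/samples.tsv    per-sample metadata
      features/<model>.tsv
      annotations/<database>.json   {"name": ..., "terms": {id: {...}}}
      enrichments/<model>/<database>.tsv
      mapping.tsv

Tables are tab-delimited, '.' decimal, ``NA`` for missing; floats use
shortest round-trip formatting so load(install(study)) reproduces values
exactly.  Installation is atomic (temp dir then rename); loading is lazy —
per-test results tables are parsed only on first access.
"""

from __future__ import annotations

import hashlib
import io
import json
import os
import shutil
import tempfile
import zipfile
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .errors import (
    ChecksumMismatchError,
    RegistryError,
    SchemaVersionError,
    StudyNotFoundError,
    ValidationFailedError,
)
from .model import (
    AnnotationDatabase,
    Assay,
    ColumnMeta,
    EnrichmentResults,
    LinkoutSpec,
    PlotHook,
    ResultsTable,
    Study,
    Test,
    validate_study,
)

__all__ = ["Registry", "StudyContainer", "install_study", "export_study",
           "install_from_archive", "load_study", "list_studies", "SCHEMA_VERSION"]

SCHEMA_VERSION = "1.0"
_NA = "NA"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, na_rep=_NA)


def _read_tsv(path: Path, key: Optional[str] = None, index_col=None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[_NA],
                     index_col=index_col, float_precision="round_trip")
    if key is not None and key in df.columns:
        df[key] = df[key].astype(str)
    return df


class Registry:
    """Directory of installed study containers, one per study name."""

    def __init__(self, root: Union[str, Path], create: bool = True):
        self.root = Path(root)
        if create:
            self.root.mkdir(parents=True, exist_ok=True)
        elif not self.root.is_dir():
            raise RegistryError(f"registry root {self.root} does not exist")

    def path_for(self, name: str) -> Path:
        return self.root / name

    def names(self) -> list[str]:
        if not self.root.is_dir():
            return []
        return sorted(p.name for p in self.root.iterdir()
                      if p.is_dir() and (p / "manifest.json").exists())


class StudyContainer:
    """Handle on one on-disk container; checksum verification and manifest access."""

    def __init__(self, path: Union[str, Path]):
        self.path = Path(path)
        manifest_path = self.path / "manifest.json"
        if not manifest_path.exists():
            raise StudyNotFoundError(f"no manifest at {self.path}")
        with open(manifest_path, encoding="utf-8") as fh:
            self.manifest = json.load(fh)

    @property
    def name(self) -> str:
        return self.manifest["study"]["name"]

    @property
    def schema_version(self) -> str:
        return self.manifest["schema_version"]

    def checksums(self) -> dict[str, str]:
        return dict(self.manifest["inventory"])

    def verify(self) -> None:
        """Recompute SHA-256 of every inventoried file; raise on any mismatch."""
        for rel, expected in self.manifest["inventory"].items():
            f = self.path / rel
            if not f.exists():
                raise ChecksumMismatchError(f"missing component file {rel}")
            actual = _sha256(f)
            if actual != expected:
                raise ChecksumMismatchError(
                    f"{rel}: checksum {actual[:12]}… != manifest {expected[:12]}…")

    def summary(self) -> dict:
        s = self.manifest["study"]
        return {"name": s["name"], "version": s["version"],
                "n_models": self.manifest["counts"]["n_models"],
                "n_tests": self.manifest["counts"]["n_tests"],
                "description": s["description"]}


# -- serialization ----------------------------------------------------------


def _serialize(study: Study, dest: Path) -> None:
    dest.mkdir(parents=True, exist_ok=True)
    inventory: list[Path] = []

    meta = {
        "study_metadata": study.metadata,
        "models": {},
        "plots": {k: h.to_dict() for k, h in study.plot_registry.items()},
    }
    for mname, model in study.models.items():
        mmeta = {"description": model.description, "metadata": model.metadata, "tests": {}}
        for tname, test in model.tests.items():
            p = dest / "results" / mname / f"{tname}.tsv"
            _write_tsv(test.results.df, p)
            inventory.append(p)
            mmeta["tests"][tname] = {
                "description": test.description,
                "metadata": test.metadata,
                "columns": {c: cm.to_dict() for c, cm in test.results.column_meta.items()},
            }
        if model.assays is not None:
            p = dest / "assays" / mname / "matrix.tsv"
            _write_tsv(model.assays.matrix.rename_axis("feature_id"), p, index=True)
            inventory.append(p)
            if model.assays.sample_meta is not None:
                p = dest / "assays" / mname / "samples.tsv"
                _write_tsv(model.assays.sample_meta.rename_axis("sample_id"), p, index=True)
                inventory.append(p)
        if model.features is not None:
            p = dest / "features" / f"{mname}.tsv"
            _write_tsv(model.features, p)
            inventory.append(p)
        for dbname, enr in model.enrichments.items():
            p = dest / "enrichments" / mname / f"{dbname}.tsv"
            _write_tsv(enr.table, p)
            inventory.append(p)
        meta["models"][mname] = mmeta

    for dbname, db in study.annotations.items():
        p = dest / "annotations" / f"{dbname}.json"
        p.parent.mkdir(parents=True, exist_ok=True)
        payload = {"name": dbname,
                   "terms": {tid: t.to_dict() for tid, t in sorted(db.terms.items())}}
        p.write_text(json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8")
        inventory.append(p)

    if study.mapping is not None:
        p = dest / "mapping.tsv"
        _write_tsv(study.mapping, p)
        inventory.append(p)

    p = dest / "metadata.json"
    p.write_text(json.dumps(meta, indent=1, sort_keys=True), encoding="utf-8")
    inventory.append(p)

    p = dest / "linkouts.json"
    p.write_text(json.dumps(
        {c: [s.to_dict() for s in specs] for c, specs in study.linkouts.items()},
        indent=1, sort_keys=True), encoding="utf-8")
    inventory.append(p)

    manifest = {
        "schema_version": SCHEMA_VERSION,
        "study": {"name": study.name, "description": study.description,
                  "version": study.version, "maintainer": study.maintainer},
        "report": study.report,
        "counts": {"n_models": study.n_models, "n_tests": study.n_tests},
        "inventory": {str(f.relative_to(dest)).replace(os.sep, "/"): _sha256(f)
                      for f in sorted(inventory)},
        "history": [],
    }
    (dest / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8")


def install_study(study: Study, registry: Registry) -> StudyContainer:
    """Validate, then write the container atomically into the registry.

    Reinstalling a name replaces the previous container (its version is kept
    in the new manifest's ``history``).  A failed install leaves the registry
    untouched.
    """
    report = validate_study(study)
    if not report.ok:
        raise ValidationFailedError(report)

    final = registry.path_for(study.name)
    prior_history: list = []
    if final.exists():
        try:
            old = StudyContainer(final)
            prior_history = old.manifest.get("history", []) + [
                {"version": old.manifest["study"]["version"]}]
        except Exception:
            prior_history = []

    tmp = Path(tempfile.mkdtemp(prefix=f".tmp-{study.name}-", dir=registry.root))
    try:
        stage = tmp / study.name
        _serialize(study, stage)
        if prior_history:
            mpath = stage / "manifest.json"
            manifest = json.loads(mpath.read_text(encoding="utf-8"))
            manifest["history"] = prior_history
            mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8")
        if final.exists():
            backup = tmp / "_old"
            os.replace(final, backup)
        os.replace(stage, final)
    except OSError as exc:
        raise RegistryError(f"could not install into {registry.root}: {exc}") from exc
    finally:
        shutil.rmtree(tmp, ignore_errors=True)
    return StudyContainer(final)


def export_study(source: Union[Study, StudyContainer, str, Path], dest: Union[str, Path],
                 registry: Optional[Registry] = None) -> Path:
    """Package a study or installed container into a single zip archive."""
    dest = Path(dest)
    if str(dest) in ("", "."):
        raise RegistryError("export destination must be a file path")
    if isinstance(source, Study):
        with tempfile.TemporaryDirectory() as tmp:
            container = install_study(source, Registry(tmp))
            return _zip_container(container, dest)
    if isinstance(source, (str, Path)):
        if registry is not None and not Path(source).exists():
            source = StudyContainer(registry.path_for(str(source)))
        else:
            source = StudyContainer(source)
    return _zip_container(source, dest)


def _zip_container(container: StudyContainer, dest: Path) -> Path:
    dest.parent.mkdir(parents=True, exist_ok=True)
    try:
        with zipfile.ZipFile(dest, "w", zipfile.ZIP_DEFLATED) as zf:
            for f in sorted(container.path.rglob("*")):
                if f.is_file():
                    zf.write(f, f"{container.name}/{f.relative_to(container.path)}")
    except OSError as exc:
        raise RegistryError(f"cannot write archive {dest}: {exc}") from exc
    return dest


def install_from_archive(archive: Union[str, Path], registry: Registry) -> StudyContainer:
    """Unpack an exported archive into the registry, verifying checksums."""
    archive = Path(archive)
    if not archive.exists():
        raise StudyNotFoundError(f"no archive at {archive}")
    tmp = Path(tempfile.mkdtemp(prefix=".import-", dir=registry.root))
    try:
        with zipfile.ZipFile(archive) as zf:
            for member in zf.namelist():
                target = (tmp / member).resolve()
                if not str(target).startswith(str(tmp.resolve())):
                    raise RegistryError(f"archive member escapes extraction dir: {member}")
            zf.extractall(tmp)
        roots = [p for p in tmp.iterdir() if p.is_dir()]
        if len(roots) != 1:
            raise RegistryError("archive must contain exactly one study directory")
        container = StudyContainer(roots[0])
        container.verify()
        final = registry.path_for(container.name)
        if final.exists():
            shutil.rmtree(final)
        os.replace(roots[0], final)
        return StudyContainer(final)
    finally:
        shutil.rmtree(tmp, ignore_errors=True)


# -- loading ----------------------------------------------------------------


def _check_schema(version: str) -> None:
    try:
        major = int(str(version).split(".")[0])
    except ValueError:
        raise SchemaVersionError(f"unparseable schema_version {version!r}")
    if major != int(SCHEMA_VERSION.split(".")[0]):
        raise SchemaVersionError(
            f"container schema {version} unsupported (reader supports {SCHEMA_VERSION}.x)")


def load_study(name_or_path: Union[str, Path], registry: Optional[Registry] = None,
               verify: bool = True) -> Study:
    """Reconstruct a Study from an installed container.

    Results tables are attached lazily: the TSV is parsed on first access to
    ``test.results.df``.  With ``verify`` (default) every inventoried file's
    checksum is validated up front.
    """
    path = Path(name_or_path)
    if not (path / "manifest.json").exists():
        if registry is None:
            raise StudyNotFoundError(f"no container at {name_or_path}")
        path = registry.path_for(str(name_or_path))
        if not (path / "manifest.json").exists():
            raise StudyNotFoundError(f"study {name_or_path!r} not in registry")
    container = StudyContainer(path)
    _check_schema(container.schema_version)
    if verify:
        container.verify()

    man = container.manifest
    meta = json.loads((path / "metadata.json").read_text(encoding="utf-8"))
    study = Study(man["study"]["name"], description=man["study"]["description"],
                  version=man["study"]["version"], maintainer=man["study"]["maintainer"],
                  metadata=meta.get("study_metadata", {}))
    if man.get("report"):
        study.set_report(man["report"])

    for dbfile in sorted((path / "annotations").glob("*.json")) if (path / "annotations").is_dir() else []:
        payload = json.loads(dbfile.read_text(encoding="utf-8"))
        study.add_annotations(AnnotationDatabase(payload["name"], payload["terms"]))

    for mname, mmeta in meta.get("models", {}).items():
        model = study.model(mname, create=True, description=mmeta.get("description", ""))
        model.metadata = mmeta.get("metadata", {})
        for tname, tmeta in mmeta.get("tests", {}).items():
            tsv = path / "results" / mname / f"{tname}.tsv"
            columns = {c: ColumnMeta.from_dict(d) for c, d in tmeta.get("columns", {}).items()}
            key = next((c for c, cm in columns.items() if cm.role == "feature_id"), None)

            def loader(p=tsv, k=key):
                return _read_tsv(p, key=k)

            # attach directly (not via add_results) so validation does not
            # force the lazy parse; the container was validated at install
            model.tests[tname] = Test(
                name=tname,
                results=ResultsTable(column_meta=columns, loader=loader),
                description=tmeta.get("description", ""),
                metadata=tmeta.get("metadata", {}),
            )
        mat = path / "assays" / mname / "matrix.tsv"
        if mat.exists():
            matrix = _read_tsv(mat, index_col=0)
            matrix.index = matrix.index.astype(str)
            matrix.index.name = None
            samples = path / "assays" / mname / "samples.tsv"
            sample_meta = None
            if samples.exists():
                sample_meta = _read_tsv(samples, index_col=0)
                sample_meta.index = sample_meta.index.astype(str)
                sample_meta.index.name = None
            model.assays = Assay(matrix, sample_meta)
        feat = path / "features" / f"{mname}.tsv"
        if feat.exists():
            df = _read_tsv(feat)
            df[df.columns[0]] = df[df.columns[0]].astype(str)
            model.features = df
        enr_dir = path / "enrichments" / mname
        if enr_dir.is_dir():
            for f in sorted(enr_dir.glob("*.tsv")):
                model.enrichments[f.stem] = EnrichmentResults(f.stem, _read_tsv(f, key="term_id"))

    mapping = path / "mapping.tsv"
    if mapping.exists():
        study.mapping = pd.read_csv(mapping, sep="\t", keep_default_na=False,
                                    na_values=[_NA], dtype=str)

    link = path / "linkouts.json"
    if link.exists():
        for col, specs in json.loads(link.read_text(encoding="utf-8")).items():
            for s in specs:
                study.linkouts.setdefault(col, []).append(
                    LinkoutSpec(column=s["column"], pattern=s["pattern"], label=s.get("label", "")))

    for name, h in meta.get("plots", {}).items():
        study.plot_registry[name] = PlotHook(name=h["name"], scope=h["scope"],
                                             ref=h.get("ref", ""),
                                             models=tuple(h.get("models", [])))
    return study


def list_studies(registry: Registry) -> list[dict]:
    """Summaries of every installed container, sorted by name; manifest-only."""
    out = []
    for name in registry.names():
        try:
            out.append(StudyContainer(registry.path_for(name)).summary())
        except Exception:
            continue
    return out
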