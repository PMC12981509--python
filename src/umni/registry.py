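"""Disease registry ingestion: CURIE-identified disease records.

Diseases are identified by CURIEs (compact URIs such as ``MONDO:0007803``).
The reader is ontology-agnostic: any ``prefix:digits`` identifier is accepted,
with a warning for non-MONDO prefixes.  Three dialects are supported:

* TSV — ``id<TAB>label[<TAB>pipe-separated-synonyms]``
* JSON — array of ``{"id": ..., "label": ..., "synonyms": [...]}``
* OBO subset — ``[Term]`` stanzas; only id, name and synonym tags are used.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .exceptions import RegistryError

CURIE_RE = re.compile(r"^[A-Za-z]+:\d+$")
_OBO_SYNONYM_RE = re.compile(r'^"(.*)"')


@dataclass(frozen=True)
class DiseaseRecord:
    """A single disease: CURIE id, primary label, optional synonyms."""

    id: str
    label: str
    synonyms: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not CURIE_RE.match(self.id):
            raise RegistryError(f"malformed CURIE identifier: {self.id!r}")
        if not self.id.startswith("MONDO:"):
            warnings.warn(
                f"non-MONDO identifier prefix in {self.id!r}; the scoring "
                "pipeline is ontology-agnostic, continuing",
                stacklevel=2,
            )
        if not self.label.strip():
            raise RegistryError(f"{self.id}: empty label")
        object.__setattr__(self, "label", self.label.strip())
        object.__setattr__(self, "synonyms", tuple(self.synonyms))


def _check_unique(records: list[DiseaseRecord]) -> list[DiseaseRecord]:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise RegistryError(f"duplicate disease id: {rec.id}")
        seen.add(rec.id)
    return records


def _load_tsv(path: Path) -> list[DiseaseRecord]:
    records = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise RegistryError(f"{path}:{lineno}: expected id<TAB>label")
            synonyms = ()
            if len(parts) >= 3 and parts[2].strip():
                synonyms = tuple(
                    s.strip() for s in parts[2].split("|") if s.strip()
                )
            try:
                records.append(DiseaseRecord(parts[0].strip(), parts[1], synonyms))
            except RegistryError as exc:
                raise RegistryError(f"{path}:{lineno}: {exc}") from exc
    return records


def _load_json(path: Path) -> list[DiseaseRecord]:
    data = json.loads(path.read_text(encoding="utf-8"))
    if not isinstance(data, list):
        raise RegistryError(f"{path}: JSON registry must be an array")
    records = []
    for i, item in enumerate(data):
        try:
            records.append(DiseaseRecord(
                str(item["id"]), str(item["label"]),
                tuple(item.get("synonyms", ())),
            ))
        except RegistryError as exc:
            raise RegistryError(f"{path}: entry {i}: {exc}") from exc
        except KeyError as exc:
            raise RegistryError(f"{path}: entry {i}: missing key {exc}") from exc
    return records


def _load_obo(path: Path) -> list[DiseaseRecord]:
    # obonet reads the full graph; we keep only id / name / synonyms.
    import obonet

    graph = obonet.read_obo(str(path), ignore_obsolete=False)
    records = []
    for node_id, attrs in graph.nodes(data=True):
        label = attrs.get("name", "")
        synonyms = []
        for syn in attrs.get("synonym", ()):
            m = _OBO_SYNONYM_RE.match(syn)
            if m:
                synonyms.append(m.group(1))
        try:
            records.append(DiseaseRecord(str(node_id), label, tuple(synonyms)))
        except RegistryError as exc:
            raise RegistryError(f"{path}: term {node_id}: {exc}") from exc
    return records


def load_disease_registry(
    path: str | Path, format: str | None = None
) -> list[DiseaseRecord]:
    """Load a disease registry, preserving input order.

    Parameters
    ----------
    path
        Input file.
    format
        ``"tsv"``, ``"json"`` or ``"obo"``.  Inferred from the file suffix
        when omitted.

    Raises
    ------
    RegistryError
        On malformed CURIEs (with line/entry location) or duplicate ids.
    """
    path = Path(path)
    if format is None:
        format = {".tsv": "tsv", ".txt": "tsv", ".json": "json",
                  ".obo": "obo"}.get(path.suffix.lower())
        if format is None:
            raise RegistryError(f"cannot infer registry format from {path.name!r}")
    loaders = {"tsv": _load_tsv, "json": _load_json, "obo": _load_obo}
    if format not in loaders:
        raise RegistryError(f"unknown registry format {format!r}")
    return _check_unique(loaders[format](path))


def write_registry_tsv(records: list[DiseaseRecord], path: str | Path) -> None:
    """Write records in the TSV dialect read by :func:`load_disease_registry`."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f"{rec.id}\t{rec.label}\t{'|'.join(rec.synonyms)}\n")
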