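"""Small-format I/O helpers: GMT gene sets and manifest checksums."""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Mapping, Sequence


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: name <tab> description <tab> member genes..."""
    groups: dict[str, list[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{line_no}: GMT record needs >=3 fields")
            name = parts[0]
            if name in groups:
                raise ValueError(f"{path}:{line_no}: duplicate group {name!r}")
            groups[name] = [g for g in parts[2:] if g]
    return groups


def write_gmt(groups: Mapping[str, Sequence[str]], path,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, members in groups.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(paths: Sequence[Path], manifest_path) -> None:
    with open(manifest_path, "w") as fh:
        fh.write("file\tsha256\n")
        for p in sorted(paths, key=lambda q: str(q)):
            fh.write(f"{Path(p).name}\t{sha256_of(p)}\n")
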