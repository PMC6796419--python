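"""GMT gene-set collection reading and writing.

A GMT file is tab-separated: set name, description, then member gene ids.
In memory a collection is a plain ``dict[str, list[str]]`` (insertion
ordered); descriptions are not retained.
"""

from __future__ import annotations

__all__ = ["read_gmt", "write_gmt"]


def read_gmt(path) -> dict[str, list[str]]:
    collection: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description "
                                 f"and at least one gene")
            name = fields[0]
            if name in collection:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            collection[name] = [g for g in fields[2:] if g]
    return collection


def write_gmt(collection: dict[str, list[str]], path,
              descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")
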