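"""Plain-text id lists (one id per line, '#' comments allowed)."""

from __future__ import annotations

__all__ = ["read_id_list"]


def read_id_list(path) -> list[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line)
    return ids
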