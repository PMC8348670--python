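"""Optional helper to download experimental structures from the PDB.

Core tests and the synthetic pipeline never need the network; this module
exists so that published structures can be pulled into a local cache when
reproducing measurements on real channels.
"""

from __future__ import annotations

import urllib.error
import urllib.request
from pathlib import Path

__all__ = ["fetch_structure", "FetchError"]

RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.{ext}"


class FetchError(RuntimeError):
    pass


def fetch_structure(
    pdb_id: str,
    cache_dir: str | Path = "pdb-cache",
    fmt: str = "pdb",
    timeout: float = 15.0,
) -> Path:
    """Download (or reuse a cached copy of) a PDB entry.

    Returns the local path; raises :class:`FetchError` when the entry
    cannot be retrieved (no network, unknown accession, ...).
    """
    pdb_id = pdb_id.lower()
    if len(pdb_id) != 4 or not pdb_id.isalnum():
        raise ValueError(f"malformed PDB accession {pdb_id!r}")
    ext = {"pdb": "pdb", "mmcif": "cif"}[fmt]
    cache = Path(cache_dir)
    cache.mkdir(parents=True, exist_ok=True)
    target = cache / f"{pdb_id}.{ext}"
    if target.exists() and target.stat().st_size > 0:
        return target
    url = RCSB_URL.format(pdb_id=pdb_id.upper(), ext=ext)
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            data = resp.read()
    except (urllib.error.URLError, OSError, TimeoutError) as exc:
        raise FetchError(f"cannot fetch {pdb_id} from {url}: {exc}") from exc
    target.write_bytes(data)
    return target
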