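"""CSV/JSON schemas for pipeline artifacts.

All tables are UTF-8 comma-delimited CSV with a leading ``# config_hash=``
comment line tying each file to the configuration that produced it; numbers
are stored at full precision.  Readers here skip the comment line.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .geography import GeographyFrame


def config_hash(config_dict: dict) -> str:
    canon = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_csv(frame: pd.DataFrame, path: Path, chash: str = "") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"# config_hash={chash}\n")
        frame.to_csv(fh, index=False)


def read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_json(obj: dict, path: Path, chash: str = "") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"config_hash": chash, **obj}
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")


def read_json(path: Path) -> dict:
    return json.loads(Path(path).read_text())


GEO_FILES = {
    "counties": "counties.csv",
    "zips": "zips.csv",
    "block_groups": "block_groups.csv",
    "states": "states.csv",
}


def write_geography(geo: GeographyFrame, out_dir: Path, chash: str = "") -> None:
    out_dir = Path(out_dir)
    write_csv(geo.states, out_dir / GEO_FILES["states"], chash)
    write_csv(geo.counties, out_dir / GEO_FILES["counties"], chash)
    write_csv(geo.zips, out_dir / GEO_FILES["zips"], chash)
    write_csv(geo.block_groups, out_dir / GEO_FILES["block_groups"], chash)


def read_geography(data_dir: Path) -> GeographyFrame:
    data_dir = Path(data_dir)
    geo = GeographyFrame(
        states=read_csv(data_dir / GEO_FILES["states"]),
        counties=read_csv(data_dir / GEO_FILES["counties"]),
        zips=read_csv(data_dir / GEO_FILES["zips"]),
        block_groups=read_csv(data_dir / GEO_FILES["block_groups"]),
    )
    geo.validate()
    return geo
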