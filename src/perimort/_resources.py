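"""Access to the small config/data files bundled with the package."""

from importlib import resources
from pathlib import Path


def data_path(name: str) -> Path:
    """Filesystem path of a bundled data file (works for installed and
    editable installs, where package data lives next to the source)."""
    ref = resources.files("perimort").joinpath("data", name)
    return Path(str(ref))
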