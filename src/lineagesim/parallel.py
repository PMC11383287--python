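"""Pluggable map over independent per-cell simulation tasks.

Results are deterministic regardless of backend or worker count: every cell's
random stream is keyed by its lineage coordinates, and maps preserve order.
"""

from __future__ import annotations


class SerialBackend:
    """Default in-process map."""

    def map(self, fn, items):
        return [fn(item) for item in items]


class JoblibBackend:
    """Process-parallel map via joblib (optional)."""

    def __init__(self, n_jobs=2):
        self.n_jobs = n_jobs

    def map(self, fn, items):
        from joblib import Parallel, delayed

        return Parallel(n_jobs=self.n_jobs)(delayed(fn)(item) for item in items)


def get_backend(spec):
    if spec is None or spec == "serial":
        return SerialBackend()
    if isinstance(spec, str) and spec.startswith("joblib"):
        n = int(spec.split(":")[1]) if ":" in spec else 2
        return JoblibBackend(n)
    if hasattr(spec, "map"):
        return spec
    raise ValueError(f"unknown parallel backend {spec!r}")
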