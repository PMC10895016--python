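"""Five-category timer instrumentation.

Every component accumulates wall-clock durations into five named
categories: ``initialisation`` (configuring the component and establishing
connections), ``simulation`` (internal computation), ``wait`` (blocking
inside channel ready/transfer calls), ``io`` (non-blocked data-exchange
time, i.e. exchange minus wait) and ``ending`` (closing connections and
writing final outputs).
"""

from __future__ import annotations

import csv
import time
from contextlib import contextmanager
from pathlib import Path

CATEGORIES = ("initialisation", "simulation", "wait", "io", "ending")

__all__ = ["CATEGORIES", "ComponentTimer", "TimerReport"]


class ComponentTimer:
    """Accumulates durations per category for one component."""

    def __init__(self, component: str):
        self.component = component
        self.totals: dict[str, float] = {c: 0.0 for c in CATEGORIES}
        self._t_created = time.perf_counter()
        self.wall: float = 0.0

    def add(self, category: str, seconds: float) -> None:
        if category not in self.totals:
            raise KeyError(f"unknown timer category {category!r}")
        self.totals[category] += max(0.0, seconds)

    @contextmanager
    def section(self, category: str):
        t0 = time.perf_counter()
        try:
            yield
        finally:
            self.add(category, time.perf_counter() - t0)

    def finish(self) -> None:
        self.wall = time.perf_counter() - self._t_created

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["component", "category", "seconds"])
            for c in CATEGORIES:
                wr.writerow([self.component, c, f"{self.totals[c]:.6f}"])
            wr.writerow([self.component, "wall", f"{self.wall:.6f}"])
        return path


class TimerReport:
    """Per-component accumulated durations for a whole run."""

    def __init__(self, data: dict[str, dict[str, float]]):
        self.data = data

    def __getitem__(self, component: str) -> dict[str, float]:
        return self.data[component]

    @property
    def components(self) -> list[str]:
        return sorted(self.data)

    def total(self, component: str) -> float:
        return sum(self.data[component].get(c, 0.0) for c in CATEGORIES)

    @classmethod
    def from_run_dir(cls, run_dir: str | Path) -> "TimerReport":
        data: dict[str, dict[str, float]] = {}
        for path in sorted(Path(run_dir, "timers").glob("*.csv")):
            with open(path, newline="") as fh:
                for row in csv.DictReader(fh):
                    data.setdefault(row["component"], {})[row["category"]] = float(
                        row["seconds"]
                    )
        return cls(data)

    def write_table(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["component", "category", "seconds"])
            for comp in self.components:
                for c in CATEGORIES:
                    wr.writerow([comp, c, f"{self.data[comp].get(c, 0.0):.6f}"])
        return path
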