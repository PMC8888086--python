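"""Packaged example datasets.

Three published datasets commonly used to benchmark lifetime models:

* ``covid_moldova`` — 28 daily COVID-19 mortality rates (per 10,000) from
  the Republic of Moldova, 25 Oct - 21 Nov 2020.
* ``jute_gauge10`` / ``jute_gauge20`` — breaking strengths of jute fibre at
  gauge lengths 10 mm and 20 mm (30 specimens each); the classic
  strength/stress pair.
* ``bank_a`` / ``bank_b`` — customer waiting times (minutes) before service
  at two banks (100 and 60 customers); the second strength/stress pair.

Values are embedded verbatim; no download is required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Dataset", "load_dataset", "list_datasets", "DATASETS"]

_COVID_MOLDOVA = (
    2.0167, 2.2917, 2.1395, 1.4134, 2.6539, 2.4832, 2.5873, 2.5588,
    2.0058, 2.4013, 2.6438, 1.6959, 1.9305, 2.0351, 1.1280, 0.2486,
    2.3525, 2.2042, 2.4167, 2.2600, 2.1084, 2.1898, 1.4898, 1.8222,
    2.1382, 1.9901, 2.0681, 2.1443,
)

_JUTE_GAUGE10 = (
    693.73, 704.66, 323.83, 778.17, 123.06, 637.66, 383.43, 151.48,
    108.94, 50.16, 671.49, 183.16, 257.44, 727.23, 291.27, 101.15,
    376.42, 163.40, 141.38, 700.74, 262.90, 353.24, 422.11, 43.93,
    590.48, 212.13, 303.90, 506.60, 530.55, 177.25,
)

_JUTE_GAUGE20 = (
    71.46, 419.02, 284.64, 585.57, 456.60, 113.85, 187.85, 688.16,
    662.66, 45.58, 578.62, 756.70, 594.29, 166.49, 99.72, 707.36,
    765.14, 187.13, 145.96, 350.70, 547.44, 116.99, 375.81, 581.60,
    119.86, 48.01, 200.16, 36.75, 244.53, 83.55,
)

_BANK_A = (
    0.8, 0.8, 1.3, 1.5, 1.8, 1.9, 1.9, 2.1, 2.6, 2.7, 2.9, 3.1, 3.2,
    3.3, 3.5, 3.6, 4.0, 4.1, 4.2, 4.2, 4.3, 4.3, 4.4, 4.4, 4.6, 4.7,
    4.7, 4.8, 4.9, 4.9, 5.0, 5.3, 5.5, 5.7, 5.7, 6.1, 6.2, 6.2, 6.2,
    6.3, 6.7, 6.9, 7.1, 7.1, 7.1, 7.1, 7.4, 7.6, 7.7, 8.0, 8.2, 8.6,
    8.6, 8.6, 8.8, 8.8, 8.9, 8.9, 9.5, 9.6, 9.7, 9.8, 10.7, 10.9,
    11.0, 11.0, 11.1, 11.2, 11.2, 11.5, 11.9, 12.4, 12.5, 12.9, 13.0,
    13.1, 13.3, 13.6, 13.7, 13.9, 14.1, 15.4, 15.4, 17.3, 17.3, 18.1,
    18.2, 18.4, 18.9, 19.0, 19.9, 20.6, 21.3, 21.4, 21.9, 23.0, 27.0,
    31.6, 33.1, 38.5,
)

_BANK_B = (
    0.1, 0.2, 0.3, 0.7, 0.9, 1.1, 1.2, 1.8, 1.9, 2.0, 2.2, 2.3, 2.3,
    2.3, 2.5, 2.6, 2.7, 2.7, 2.9, 3.1, 3.1, 3.2, 3.4, 3.4, 3.5, 3.9,
    4.0, 4.2, 4.5, 4.7, 5.3, 5.6, 5.6, 6.2, 6.3, 6.6, 6.8, 7.3, 7.5,
    7.7, 7.7, 8.0, 8.0, 8.5, 8.5, 8.7, 9.5, 10.7, 10.9, 11.0, 12.1,
    12.3, 12.8, 12.9, 13.2, 13.7, 14.5, 16.0, 16.5, 28.0,
)


@dataclass(frozen=True)
class Dataset:
    name: str
    values: np.ndarray
    description: str

    @property
    def n(self) -> int:
        return self.values.size


_RAW = {
    "covid_moldova": (
        _COVID_MOLDOVA,
        "Daily COVID-19 mortality rate per 10,000, Republic of Moldova, "
        "25 Oct - 21 Nov 2020 (n=28)",
    ),
    "jute_gauge10": (
        _JUTE_GAUGE10,
        "Breaking strength of jute fibre at gauge length 10 mm (n=30); "
        "strength sample of the jute stress-strength pair",
    ),
    "jute_gauge20": (
        _JUTE_GAUGE20,
        "Breaking strength of jute fibre at gauge length 20 mm (n=30); "
        "stress sample of the jute stress-strength pair",
    ),
    "bank_a": (
        _BANK_A,
        "Customer waiting time (minutes) before service at bank A (n=100); "
        "strength sample of the bank stress-strength pair",
    ),
    "bank_b": (
        _BANK_B,
        "Customer waiting time (minutes) before service at bank B (n=60); "
        "stress sample of the bank stress-strength pair",
    ),
}

DATASETS = tuple(_RAW)


def load_dataset(name: str) -> Dataset:
    """Return a packaged dataset by name; unknown names list the options."""
    try:
        values, desc = _RAW[name]
    except KeyError:
        raise KeyError(
            f"unknown dataset {name!r}; available: {', '.join(DATASETS)}"
        ) from None
    arr = np.asarray(values, dtype=float)
    arr.setflags(write=False)
    return Dataset(name=name, values=arr, description=desc)


def list_datasets() -> dict[str, str]:
    return {name: desc for name, (_, desc) in _RAW.items()}
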