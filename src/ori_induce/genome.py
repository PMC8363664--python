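"""Fixed-width genome binning.

Every track in the pipeline lives on a :class:`GenomeBinning`: an ordered set of
chromosomes, each partitioned into consecutive, non-overlapping bins of one
fixed width (10 kb by default throughout the package). Trailing base pairs that
do not fill a whole bin are dropped, so a chromosome of length L contributes
``L // bin_width_bp`` bins. Bins flagged as *masked* (unmappable / repetitive
regions) are excluded from normalisation, standard-deviation estimation and
peak calling, but still occupy index space so that global and per-chromosome
bin indices map one-to-one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class GenomeBinning:
    """Partition of a multi-chromosome genome into fixed-width bins.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    bin_width_bp
        Bin width in base pairs; must be positive.
    masked
        Boolean flag per *global* bin (True = masked). Defaults to all
        unmasked.
    """

    chromosomes: list[tuple[str, int]]
    bin_width_bp: int = 10_000
    masked: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.bin_width_bp <= 0:
            raise ValueError(f"bin_width_bp must be positive, got {self.bin_width_bp}")
        if not self.chromosomes:
            raise ValueError("at least one chromosome is required")
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length < self.bin_width_bp:
                raise ValueError(
                    f"chromosome {name!r} ({length} bp) is shorter than one bin "
                    f"({self.bin_width_bp} bp)"
                )
        self._n_bins = np.array(
            [length // self.bin_width_bp for _, length in self.chromosomes], dtype=np.int64
        )
        self._offsets = np.concatenate([[0], np.cumsum(self._n_bins)])
        self._index = {name: i for i, (name, _) in enumerate(self.chromosomes)}
        if self.masked is None:
            self.masked = np.zeros(self.n_bins_total, dtype=bool)
        else:
            self.masked = np.asarray(self.masked, dtype=bool)
            if self.masked.shape != (self.n_bins_total,):
                raise ValueError(
                    f"masked must have one flag per bin ({self.n_bins_total}), "
                    f"got shape {self.masked.shape}"
                )

    # -- index arithmetic ---------------------------------------------------

    @property
    def n_bins_total(self) -> int:
        return int(self._offsets[-1])

    @property
    def chromosome_names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    def n_bins(self, chromosome: str) -> int:
        return int(self._n_bins[self._index[chromosome]])

    def chrom_slice(self, chromosome: str) -> slice:
        """Slice of any global per-bin array covering one chromosome."""
        i = self._index[chromosome]
        return slice(int(self._offsets[i]), int(self._offsets[i + 1]))

    def global_index(self, chromosome: str, local_bin: int) -> int:
        i = self._index[chromosome]
        if not 0 <= local_bin < self._n_bins[i]:
            raise IndexError(f"bin {local_bin} out of range for {chromosome}")
        return int(self._offsets[i]) + local_bin

    def local_index(self, global_bin: int) -> tuple[str, int]:
        if not 0 <= global_bin < self.n_bins_total:
            raise IndexError(f"global bin {global_bin} out of range")
        i = int(np.searchsorted(self._offsets, global_bin, side="right")) - 1
        return self.chromosomes[i][0], int(global_bin - self._offsets[i])

    def bin_start(self, chromosome: str, local_bin: int) -> int:
        """0-based start coordinate of a bin."""
        self.global_index(chromosome, local_bin)  # bounds check
        return local_bin * self.bin_width_bp

    def locate(self, chromosome: str, position_bp: int) -> int | None:
        """Global bin containing a position, or None if it falls in the
        dropped trailing partial bin / off the chromosome."""
        if chromosome not in self._index:
            raise KeyError(f"unknown chromosome {chromosome!r}")
        if position_bp < 0:
            raise ValueError(f"negative position {position_bp}")
        local = position_bp // self.bin_width_bp
        i = self._index[chromosome]
        if local >= self._n_bins[i]:
            return None
        return int(self._offsets[i]) + int(local)

    def same_binning(self, other: "GenomeBinning") -> bool:
        return (
            self.chromosomes == other.chromosomes
            and self.bin_width_bp == other.bin_width_bp
            and bool(np.array_equal(self.masked, other.masked))
        )

    def bin_table(self) -> "np.recarray":
        """(chromosome, start, end, masked) rows for every bin, for writers."""
        chroms: list[str] = []
        starts: list[int] = []
        w = self.bin_width_bp
        for name, _ in self.chromosomes:
            n = self.n_bins(name)
            chroms.extend([name] * n)
            starts.extend(range(0, n * w, w))
        rec = np.rec.fromarrays(
            [np.array(chroms), np.array(starts), np.array(starts) + w, self.masked],
            names=("chromosome", "start", "end", "masked"),
        )
        return rec
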