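# gdgtbudget

Mass-balance attribution of archaeal ether lipids in ocean depth profiles.

Marine planktonic archaea fall into two dominant groups with very different
depth habitats: MGI Thaumarchaeota (mostly within and below the deep
chlorophyll maximum, DCM) and MGII/III Thermoplasmatota (abundant up to the
surface). Their membrane-spanning tetraether lipids (GDGTs, including the
Thaumarchaeota biomarker crenarchaeol) are the basis of the TEX86
sea-surface-temperature proxy, so it matters which group actually makes the
GDGTs found in surface waters. `gdgtbudget` implements the quantitative
chain that answers that question from paired lipid and DNA measurements on
the same filters:

1. **Lipid quantification** (`lipid_quant`) — internal-standard (C46) LC-MS
   SIM quantification, `conc = (A/A_IS) · RF · m_IS / V`, with response
   factors RF = 1.5 (tetraethers) and 4.0 (archeol), an inclusive SN ≥ 5
   reporting filter and a 0.00060 ng/L limit of quantification. Intact polar
   (IP) lipids — the living-biomass signal — come from subtracting the
   non-hydrolyzed (core) from the acid-hydrolyzed (total) fraction;
   per-compound negatives are retained but clamped to zero in the IP sum.
   Also: within-head-group-class relative distributions and the TEX86 ring
   index.
2. **Community quantification** (`community`) — amplicon (AASV) counts
   anchored on ddPCR totals give absolute SSU rRNA copies/L per archaeal
   group; copies → cells at one rRNA copy per cell; per-sample sequencing
   detection limit `100 / read_depth` percent; Shannon diversity, richness
   and rarefaction.
3. **Lipid budget** (`budget`) — the mass balance. Per-cell quotas
   `q = IP / cells`, expected pools `cells · q`, attribution fractions,
   inferred abundance of a hypothesized producer `IP / q`, fraction of the
   theoretical whole-membrane lipid content (1.4 × 10⁻⁶ ng/cell for a 500 nm
   cell), and a detectability verdict: would the inferred population exceed
   the sequencing detection limit?
4. **Statistics** (`stats`) — from-scratch Bray-Curtis distances,
   non-metric multidimensional scaling (Kruskal stress-1, isotonic
   regression by pool-adjacent-violators, random restarts) and the
   one-tailed permutation Mantel test.
5. **Synthetic data** (`synthetic`) — a generator that emulates the
   stratified two-cluster depth structure (Thaumarchaeota absent above the
   DCM, 100–1000× lower lipid concentrations there, occasional negative IP
   estimates from fraction-specific matrix effects) with full ground truth
   for recovery testing.

A `click` CLI (`gdgtbudget`) orchestrates everything end to end.

## Worked example

Simulate a two-station depth profile and run the budget:

```sh
gdgtbudget simulate --seed 7 --out demo/inputs
gdgtbudget budget \
    --peaks demo/inputs/peaks.csv --counts demo/inputs/counts.tsv \
    --taxonomy demo/inputs/taxonomy.tsv --ddpcr demo/inputs/ddpcr.csv \
    --out demo/out
```

prints (abridged):

```
Ether lipid mass-balance report
================================
Surface Thermoplasmatota quota: 7.31e-11 to 1.68e-09 ng/cell (mean 9.15e-10; n=10)

[surface] SYN1_005m  IP-ethers 0.00976 ng/L
  quota 1.68e-09 ng/cell = 0.12% of theoretical membrane
  inferred Thaumarchaeota 7.68e+03 copies/L -> 0.13% vs limit 0.00269% (detectable)
...
[subsurface] SYN1_125m  IP-ethers 5.54 ng/L
  expected pool 5.26 ng/L; MGII/III attribution 0.0941%; measured/expected 1.05
```

Reading the numbers: above the DCM the IP-ether pool divided by the
Thermoplasmatota cell density gives an apparent quota of order 10⁻⁹ ng/cell —
three orders of magnitude below both the cultured-Thaumarchaeota quota
(1.27 × 10⁻⁶ ng/cell) and the theoretical membrane content, i.e. at most
~0.1% of a Thermoplasmatota membrane. Had Thaumarchaeota produced those
lipids, the cell densities required (~10³ copies/L, "inferred Thaumarchaeota")
would sit well above the sequencing detection limit — so their absence from
the amplicon data is informative, not a sensitivity artifact. Within/below
the DCM, expected pools computed from cell densities and quotas attribute
well under 1% of the IP-ethers to MGII/III Thermoplasmatota.

`gdgtbudget all --out demo/full --seed 7` additionally writes NMDS
coordinates for the community and lipid Bray-Curtis matrices, the Mantel
statistics linking them (on this dataset r = 0.87, p = 0.001 with 999
permutations), and a provenance record; re-running with the same seed
reproduces every file byte for byte.

The same subcommands run on your own tables: a peak CSV/TSV with columns
`sample_id, fraction, compound, headgroup_class, adduct, peak_area,
noise_level, is_area, is_mass_ng, volume_L`, an AASV count TSV plus
two-column taxonomy TSV, and a ddPCR CSV (`sample_id, copies_per_L`).

## Documentation

See `docs/methods.md` for the model assumptions, parameter defaults and
units, the synthetic generator's noise model, and known limitations.
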