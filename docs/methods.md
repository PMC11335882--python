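# Methods

This note documents the models and procedures the package implements,
the defaults that matter, what the synthetic-data generators do and do
not emulate, and the numerical choices made where the design was open.

## Fire Weather Index System

The daily updates are the standard published closed-form equations for
FFMC, DMC and DC and the ISI/BUI/FWI combinations, with the
conventional mid-latitude monthly day-length factors (tabulated at the
top of `fwi.py`). All updates are vectorised over grid cells; cells
are fully independent, and the test suite holds the grid engine to
within 1e−9 of an independent scalar transcription of the same
equations.

Startup/shutdown follow consecutive-day rules on daily maximum
temperature: the season turns **on the day after** the third
consecutive day above 12 °C and off the day after the third
consecutive day below 5 °C. Emitting indices only once the triggering
run is complete keeps the rule causal (no use of future temperatures);
both thresholds and the run length are configurable. Cells outside
the season report missing indices rather than zeros so percentile
climatologies are not biased by a mass at zero; the moisture codes are
held, and precipitation is accumulated for overwintering.

Drought Code overwintering uses the moisture-equivalent carryover
Q_spring = a·Q_fall + b·(3.94·r_w) with DC = 400·ln(800/Q) clamped at
zero. The defaults a = b = 0.75 are mid-range values of the
conventional carryover/effectiveness classes; both are configurable
and nothing downstream assumes a particular choice. Where a cell has
no previous season, startup codes default to the conventional agency
values FFMC 85, DMC 6, DC 15.

Noon sampling: gridded inputs are expected as local-solar-noon values
with trailing-24-h precipitation. Where hourly data must be reduced,
the package convention is a whole-hour longitude offset,
round(lon/15°) — the same convention used to correct hotspot detection
times.

## Climatology and extremes

FWI₉₅ is the per-cell 95th percentile of in-season FWI over the
baseline years, using linear interpolation between order statistics
(verified against brute-force sorting). Cells with fewer than 100
in-season baseline days are masked — below that the upper tail of the
empirical distribution is too ragged for a stable 95th percentile.

The daily extent of extreme fire weather sums cell areas (spherical:
R²·Δλ·(sin φ₊ − sin φ₋), R = 6371 km) where the cell is season-active,
forested (canopy cover > 0.20) and FWI > FWI₉₅; the reported
proportion divides by the region's total forested area, matching the
operational definition. For the stationarity check the package
normalises instead by the *season-active* forested area, since
off-season cells cannot exceed their percentile by construction and
would dilute the 5 % property.

VPD uses the improved-Magnus saturation vapour pressure over water
(6.1094 hPa, 17.625, 243.04 °C); dewpoints above the temperature are
clamped with a warning. Seasonal anomalies and ranks are computed on
May–October means; for precipitation, rank 1 is the driest year
(direction configurable). Standardized anomalies of monthly fields
(e.g. monthly-mean DC) use the baseline mean and SD per cell; a
month-end variant is available where monthly means are not wanted.

Extent-vs-burn association uses Spearman rank correlation with midrank
ties, on dates present in both series; fewer than 3 paired days yields
a flagged NaN.

## Blocking proxy

Daily 500-hPa height anomalies are standardized against a per-cell,
per-calendar-month baseline climatology (a 3-month pooled variant is
available; "seasonal" is not otherwise defined). Cells above 1 SD are
grouped by 8-neighbour connectivity and linked day to day when
footprints share at least one cell; when an event's footprint splits,
the largest-overlap component inherits the event and the others spawn
new ones. Events qualify with ≥ 5 days persistence and a footprint
reaching ≥ 100 000 km² at some time; the blocking-day map counts, per
cell, the days under any qualifying event within April–October.
Linkage rule and connectivity are configurable and recorded in output.

## Snowmelt and flash drought

Snowmelt timing is the first day of the longest snow-free run of the
calendar year; runs do not wrap across years, ties go to the earliest
run, and a never-snow-covered cell returns day 1 flagged degenerate.
Departures subtract the baseline-mean melt day (2004–2022-style).

Maximum drying is measured endpoint-to-endpoint over a 14-day window
(day t minus day t+13), maximised over windows lying wholly inside the
May 1 – June 30 search interval, floored at zero (wetting is not
reported as negative drying). The onset date is the midpoint of the
earliest maximal window, taken as t + 6 for the 14-day window. The
endpoint convention and the whole-window-inside-interval rule are
package choices where the definition was open; both are parameters.

## Burned area from hotspots

All vector geometry is projected to a spherical Albers equal-area
conic (standard parallels 50°/70°N, origin 40°N/96°W, R = 6371 km)
implemented in-package, so metre radii and hectare areas are exact in
the working plane. Geometries are snapped to 1 m before dissolving to
avoid slivers.

Buffer-radius optimisation evaluates every candidate (r_out, r_in)
pair exhaustively per ecozone and maximises intersection-over-union
against the reference perimeters — the IoU objective simultaneously
maximises the intersecting area and penalises commission and omission;
ties break to the smallest r_out, then r_in. Calibration factors are
unweighted means of yearly reference/buffered area ratios per ecozone
(area-weighted pooling is an option); strata with zero buffered area
are skipped with a warning. Cleaning erases water bodies first and
then drops polygons under 1 ha, so erasure fragments are themselves
subject to the filter. The hybrid total is Σ reference areas +
Σ (buffered area × ecozone factor), with per-fire provenance retained
and a hard error if a fire appears in both sources.

Land-cover proportions assign raster pixels to polygons by
centre-in-polygon membership; proportions are over fuel classes and
the nonfuel fraction (Water, Rock) is reported separately.

## Day-of-burn kriging

Hotspot times are shifted to local standard time by the longitude
offset and detections with a local date before April 1 are dropped as
false. Per fire (≥ 500 ha by convention), date ordinals are
interpolated by ordinary kriging to a 180-m grid whose pixel
boundaries are snapped to a fixed national anchor, so grids from
different runs and fires are co-registered. The variogram (exponential
by default; spherical and Gaussian available) is fitted per fire to
the empirical variogram of the dates; with up to `max_neighbors`
points the system is solved globally with one factorisation, otherwise
a moving neighbourhood of nearest samples is used. Duplicate
locations are averaged to keep the system nonsingular; with zero
nugget, kriging honours the data exactly at sample points.
Predictions are clamped to the fire's observed date range and rounded
half-up to whole days. Fires with fewer than 5 hotspots fall back to
nearest-neighbour date assignment, flagged in the output. Daily-area
series sum pixel areas by interpolated day, so each fire's series sums
exactly to its footprint area; overlapping grids are an error.

## Fire-level summaries

Size classes are right-closed intervals — a fire must strictly exceed
200 ha to be "large" and 50 000 ha to be "very large"; containment
means finishing strictly under 200 ha. Duration is out date minus
start date plus one; its "90 % interval" is the 5th–95th percentile of
the per-fire duration distribution (a bootstrap option exists; the
distribution quantiles are the default because the intervals being
reproduced behave like distribution ranges). A fire's potential
spread days count the days in [start, out] on which any overlapping
grid cell exceeds its own FWI₉₅; fires without a footprint map to the
nearest cell of their centroid. The size/spread-days power law is fit
by least squares of log size on log (spread days + 1). PM2.5
exceedance days count days strictly above 27 µg m⁻³.

## Synthetic data and what passing tests mean

Weather is a seasonal cycle (annual mean 5 °C, amplitude 18 °C, peak
near July 19) plus per-cell AR(1) anomalies (ρ = 0.7, SD 3 °C), RH
anticorrelated with the temperature anomaly, gamma wind, and
precipitation as thinned gamma events (30 % wet days, mean ≈ 4 mm);
daily maxima run 5 °C above noon values so the season starts near
mid-May under the 12 °C rule. This is stationary year over year by
construction, which is exactly what the 5 % exceedance property needs;
it does not emulate spatial correlation of weather, frontal passages,
or climate trends, so passing tests demonstrate the *statistics*, not
realism of any particular season.

Height fields carry full AR(1) variability (SD 60 m) in baseline years
so the climatological SD is realistic; in the evaluation year the
background anomalies are damped and clipped well below one SD so that
implanted ridges are the only above-threshold anomalies — that is what
makes exact event recovery a meaningful check of the tracker rather
than of luck with noise. Snow series are deterministic around
per-cell melt days; soil-moisture series are slow wetting plus one
strict 14-day linear drying ramp per cell, making the implanted ramp
the unique maximal window. Fires grow as expanding ellipses with
area linear in time, guaranteeing a monotone day-of-burn field;
hotspots are sampled in each day's newly burned band at one per 50 ha
with timing jitter, plus planted pre-April false detections and
sub-hectare sliver polygons for the filters to remove. Real hotspot
data have omission/commission patterns (cloud, view angle) the
generator does not model.

Problem sizes used by the acceptance studies — a 20×20 grid with a
30-year baseline and 5 evaluation years, a 10-implant blocking roster,
3 historical years × 16 fires for calibration, a 20-fire target year,
and one 100 kha/20-day fire (~2 000 hotspots, ~31 000 pixels) for
kriging — were chosen so each statistic has enough sample to be
diagnostic while a full run stays around a minute.

## Known limitations

- Hourly-to-noon reduction is by longitude offset only; no true solar
  geometry or daylight-saving handling.
- The blocking tracker's largest-overlap inheritance can relabel
  events under complex split–merge sequences; counts are unaffected.
- Kriging assumes isotropy; elongated fire runs under wind-driven
  spread would benefit from an anisotropic variogram.
- The calibration transfer from historical to target fires assumes the
  same hotspot sampling character; sensor changes between eras would
  need era-specific radii (the sensor tag is carried for this).
- GeoTIFF is not written; rasters are exchanged as classic NetCDF.
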