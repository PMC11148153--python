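# Published adult-assessment trap counts, Cheboygan River watershed study
# streams (Pigeon, Sturgeon, Maple Rivers), 2013-2022.
# sterile_recaptured is blank for no-release years (no recapture count exists).
# abundance_est carries the published abundance where it was derived from
# external survey estimates rather than the Petersen arithmetic on this row's
# counts (all no-release years, plus Pigeon 2021/2022, Sturgeon 2017, Maple 2021).
# ratio_censored_at=40 marks ratios published only as exceeding 40:1.
# ambiguous=True marks rows whose published derived values are internally
# inconsistent; they are processed but excluded from exact-match tests.
stream,year,sterile_released,sterile_recaptured,wild_captured,wild_males_observed,abundance_est,ratio_censored_at,ambiguous
Pigeon,2013,0,,2,,21,,False
Pigeon,2014,0,,0,,,,False
Pigeon,2015,0,,1,,10,,False
Pigeon,2016,0,,0,,,,False
Pigeon,2017,1425,413,2,,8,,True
Pigeon,2018,1338,428,4,,12,,True
Pigeon,2019,360,72,1,,,,True
Pigeon,2020,0,,0,,,,False
Pigeon,2021,275,28,9,,90,,False
Pigeon,2022,525,74,15,,110,,False
Sturgeon,2013,0,,1,,10,,False
Sturgeon,2014,0,,0,,,,False
Sturgeon,2015,0,,0,,,,False
Sturgeon,2016,0,,0,,,,False
Sturgeon,2017,1425,399,1,,1,,True
Sturgeon,2018,1350,257,1,,,,False
Sturgeon,2019,908,163,6,,,,False
Sturgeon,2020,0,,0,,,,False
Sturgeon,2021,528,23,0,,,40,False
Sturgeon,2022,1400,70,3,2,,,False
Maple,2013,0,,1,,5,,False
Maple,2014,0,,2,,26,,False
Maple,2015,0,,2,,23,,False
Maple,2016,0,,0,,,,False
Maple,2017,830,498,0,,,40,False
Maple,2018,813,203,0,,,40,False
Maple,2019,628,44,0,,,40,False
Maple,2020,0,,1,,,,False
Maple,2021,666,53,1,,5,40,False
Maple,2022,1400,700,0,,,40,False
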