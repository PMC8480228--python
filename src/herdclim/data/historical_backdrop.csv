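Model,Scenario,Region,Variable,Unit,1850,1851,1852,1853,1854,1855,1856,1857,1858,1859,1860,1861,1862,1863,1864,1865,1866,1867,1868,1869,1870,1871,1872,1873,1874,1875,1876,1877,1878,1879,1880,1881,1882,1883,1884,1885,1886,1887,1888,1889,1890,1891,1892,1893,1894,1895,1896,1897,1898,1899,1900,1901,1902,1903,1904,1905,1906,1907,1908,1909,1910,1911,1912,1913,1914,1915,1916,1917,1918,1919,1920,1921,1922,1923,1924,1925,1926,1927,1928,1929,1930,1931,1932,1933,1934,1935,1936,1937,1938,1939,1940,1941,1942,1943,1944,1945,1946,1947,1948,1949,1950,1951,1952,1953,1954,1955,1956,1957,1958,1959,1960,1961,1962,1963,1964,1965,1966,1967,1968,1969,1970,1971,1972,1973,1974,1975,1976,1977,1978,1979,1980,1981,1982,1983,1984,1985,1986,1987,1988,1989,1990,1991,1992,1993,1994,1995,1996,1997,1998,1999,2000,2001,2002,2003,2004,2005,2006,2007,2008,2009,2010,2011,2012,2013,2014,2015,2016,2017,2018,2019,2020
herdclim,historical (stylized),World,Emissions|CO2,Gt CO2/yr,0.2,0.206731854,0.2136902973,0.2208829567,0.2283177158,0.2360027235,0.2439464029,0.2521574607,0.2606448968,0.2694180138,0.2784864274,0.2878600773,0.2975492374,0.3075645275,0.317916925,0.3286177766,0.3396788111,0.351112152,0.3629303307,0.3751463007,0.3877734513,0.4008256227,0.4143171205,0.4282627324,0.4426777433,0.457577953,0.4729796929,0.4888998441,0.505355856,0.5223657652,0.5399482156,0.5581224784,0.5769084736,0.5963267917,0.6163987162,0.6371462471,0.6585921247,0.6807598548,0.7036737346,0.7273588789,0.7518412478,0.7771476754,0.8033058989,0.8303445891,0.8582933818,0.8871829105,0.9170448397,0.9479118996,0.9798179222,1.012797878,1.046887916,1.082125399,1.11854895,1.156198491,1.195115288,1.235341996,1.276922706,1.319902992,1.364329963,1.410252314,1.457720378,1.506786181,1.557503504,1.609927936,1.664116935,1.720129896,1.778028213,1.837875344,1.899736887,1.963680644,2.029776701,2.098097503,2.168717933,2.241715396,2.3171699,2.395164147,2.475783624,2.559116694,2.645254694,2.734292036,2.82632631,2.92145839,3.019792547,3.12143656,3.226501836,3.335103533,3.447360683,3.563396327,3.683337646,3.807316103,3.935467584,4.06793255,4.20485619,4.34638858,4.492684847,4.64390534,4.800215803,4.961787563,5.128797711,5.301429298,5.479871539,5.664320014,5.854976891,6.05205114,6.255758763,6.466323037,6.68397475,6.908952461,7.141502758,7.381880528,7.630349238,7.887181223,8.152657986,8.427070503,8.710719545,9.003916006,9.306981246,9.620247442,9.944057948,10.27876768,10.6247435,10.98236461,11.35202298,11.73412379,12.12908583,12.53734201,12.95933979,13.39554171,13.84642586,14.31248645,14.79423429,15.29219742,15.80692162,16.33897107,16.88892891,17.45739793,18.0450012,18.65238277,19.28020835,19.92916609,20.59996728,21.29334714,22.01006566,22.7509084,23.51668737,24.3082419,25.12643958,25.9721772,26.84638172,27.75001134,28.68405646,28.97089703,29.260606,29.55321206,29.84874418,30.14723162,30.44870394,30.75319097,31.06072288,31.37133011,31.68504341,32.00189385,32.32191279,32.64513191,32.97158323,33.30129907,33.63431206,33.97065518,34.31036173,34.65346535,35
herdclim,historical (stylized),World,Emissions|CH4|Livestock,Mt CH4/yr,30,30.25300945,30.5081527,30.76544774,31.02491271,31.28656592,31.55042582,31.81651102,32.08484029,32.35543255,32.6283069,32.90348257,33.18097897,33.46081569,33.74301244,34.02758915,34.31456588,34.60396286,34.89580052,35.19009944,35.48688037,35.78616424,36.08797217,36.39232544,36.69924552,37.00875406,37.32087288,37.63562401,37.95302963,38.27311214,38.59589411,38.92139832,39.24964771,39.58066544,39.91447486,40.25109951,40.59056314,40.93288968,41.27810328,41.62622829,41.97728927,42.33131097,42.68831837,43.04833664,43.41139118,43.77750759,44.1467117,44.51902955,44.8944874,45.27311172,45.65492923,46.03996686,46.42825176,46.81981131,47.21467314,47.6128651,48.01441527,48.41935197,48.82770376,49.23949945,49.65476808,50.07353894,50.49584157,50.92170574,51.35116151,51.78423916,52.22096923,52.66138253,53.10551011,53.55338332,54.00503373,54.4604932,54.91979386,55.38296809,55.85004858,56.32106826,56.79606035,57.27505836,57.75809606,58.24520754,58.73642715,59.23178953,59.73132962,60.23508266,60.74308417,61.25536999,61.77197625,62.29293939,62.81829614,63.34808357,63.88233904,64.42110023,64.96440514,65.5122921,66.06479974,66.62196704,67.18383329,67.75043813,68.32182151,68.89802373,69.47908545,70.06504763,70.65595161,71.25183907,71.85275204,72.45873289,73.06982437,73.68606959,74.307512,74.93419543,75.5661641,76.20346256,76.84613578,77.49422908,78.14778816,78.80685914,79.47148849,80.14172309,80.81761021,81.49919752,82.18653311,82.87966544,83.5786434,84.2835163,84.99433385,85.71114619,86.43400387,87.16295787,87.89805962,88.63936096,89.38691417,90.14077198,90.90098757,91.66761454,92.44070698,93.22031941,94.00650682,94.79932465,95.59882883,96.40507575,97.21812227,98.03802574,98.86484399,99.69863533,100.5394586,101.387373,102.2424385,103.1047153,103.9742642,104.8511466,105.7354243,106.4312337,107.1316219,107.8366192,108.5462558,109.2605624,109.9795695,110.7033081,111.4318095,112.1651049,112.9032258,113.6462041,114.3940716,115.1468607,115.9046035,116.6673329,117.4350815,118.2078823,118.9857688,119.7687742,120.5569324
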