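site,group,period,prop_males,n_adults,n_males,fdi,mm_ago,fm_ago,n_aggressive,pct_unknown
FBV,CH,2007,0.33,6,2,0.13,0.33,0.33,21,23.30
FBV,CH,2007/08,0.29,7,2,0.40,0.15,0.09,60,21.40
FBV,CH,2009/2010,0.50,8,4,0.63,0.44,0.76,85,3.60
FBV,CH,2010 b,0.50,8,4,0.72,0.68,0.57,60,21.40
FBV,ZA,2006 a,0.56,9,5,0.73,0.88,0.48,67,18.00
FBV,ZA,2006 b,0.20,5,1,0.00,0.00,0.00,10,25.00
FBV,ZA,2006/2008,0.25,4,1,0.00,0.00,0.00,28,0.00
FBV,ZA,2009/2010,0.50,8,4,0.50,0.31,0.93,55,13.90
PECB,LAR,2002,0.33,6,2,0.44,0.78,0.13,34,16.70
PECB,PIM,2010,0.29,7,2,0.15,0.75,0.00,28,28.60
PECB,TES,2010,0.42,12,5,0.53,0.81,0.20,26,39.40
UNA,PRIN,2012,0.38,16,6,0.13,0.39,0.64,58,33.30
UNA,PRIN,2013,0.38,16,6,0.23,0.46,0.63,55,36.70
UNA,PRIN,2016,0.36,11,4,0.33,0.37,0.44,41,31.80
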