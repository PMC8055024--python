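site,group,study_period,n_males,n_females,hours
FBV,CH,February 2007 to July 2007,2,4,215
FBV,CH,August 2007 to April 2008,2,5,327
FBV,CH,January 2009 to March 2010,4,4,691
FBV,CH,April 2010 to August 2010,4,4,402
FBV,ZA,April to May 2006,5,4,295
FBV,ZA,May 2006 to July 2006,1,4,100
FBV,ZA,August 2006 to April 2008,1,3,1171
FBV,ZA,January 2009 to December 2010,4,4,733
PECB,LAR,November 2001 to December 2002,2,4,805
PECB,PIM,January 2009 to August 2010,2,5,516
PECB,TES,January 2009 to August 2010,5,7,380
UNA,PRIN,December 2011 to July 2012,6,10,1050
UNA,PRIN,August 2012 to March 2013,6,10,1075
UNA,PRIN,April 2015 to March 2016,4,7,1308
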